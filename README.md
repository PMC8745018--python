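# abquant

Quantification of β-amyloid (Aβ) proteoforms from tandem-MS data.

The centerpiece is a label-free estimator of the isoAsp7-Aβ fraction.
Asp7 isomerization is mass silent, but it enhances backbone cleavage near
the modified residue in CID, raising the intensities of the b6, b7 and y10
fragment ions of the Aβ(1–16) peptide relative to iso-insensitive "base"
ions (b11, y11). The marker/base intensity ratio therefore encodes the
isomerized fraction; a calibration curve built from designed binary
norm/iso mixtures (0–100 % in 10 % steps) converts an observed ratio into a
percentage by inverse prediction.

Around it, the package provides proteoform accounting from PSM-level
quantification tables (terminal truncation distributions, PTM site
occupancies, LysC missed-cleavage fractions, per-age abundance series),
cohort trend statistics (Kendall τ-b, Mann–Whitney U, z-score outliers,
accumulation-phase grouping), and a synthetic-data module that generates
everything needed to exercise the pipeline offline with known ground truth.

## Modules

| module | contents |
| --- | --- |
| `abquant.reference` | Aβ sequence constants (human/murine, 1-based Aβ numbering, M(−1) supported), modification registry, b/y fragment-mass arithmetic |
| `abquant.spectra` | MGF reader/writer, spectrum accumulation, nearest-peak fragment matching (default tolerance 0.05 Da) |
| `abquant.isoquant` | marker/base ratios, calibration fitting (linear with a shape-constrained monotone fallback), inverse prediction with uncertainty, matrix-effect comparison of curves |
| `abquant.proteoforms` | PSM table I/O and validation, truncation/PTM/missed-cleavage summaries, abundance time series |
| `abquant.dynamics` | Kendall τ-b trend (tie-corrected, exact p for small tie-free samples), Mann–Whitney U, z>3 outlier flagging, age-phase bins |
| `abquant.synthdata` | simulated CID spectra of norm/iso mixtures, simulated ageing-cohort PSM tables and replicate spectra, fixture-bundle writer |

## CLI

```bash
# write a complete synthetic fixture (MGFs, PSM table, design, ground truth)
abquant simulate --seed 42 --out fixtures/

# fit the calibration curve from the designed mixtures
abquant calibrate --design fixtures/calibration/design.csv \
    --spectra fixtures/calibration --out curve.json

# per-sample isoAsp7 estimates (one MGF file per sample)
abquant quantify-iso --curve curve.json --spectra fixtures/cohort \
    --marker b6 --base b11 --tolerance-da 0.05 --out estimates.csv

# trend against age, and pairwise phase-group comparison
abquant trend --input estimates_with_ages.csv --out trend.json
abquant compare-groups --input estimates_with_ages.csv --out groups.json
```

## Notes

- All ions are singly protonated monoisotopic species (MALDI conditions);
  only b/y series are modeled.
- `iso_asp` is a zero-mass flag: it never shifts any m/z, which is exactly
  why the fragment-ratio method exists.
- Aβ coordinates are 1-based with no position 0; the Met preceding D1 is
  position −1.
- Sample estimates default to the mean of per-spectrum ratios; ratio of
  accumulated intensities is available via `averaging="ratio_of_sums"`.
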