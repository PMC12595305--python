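# fibrilkit

Quantitative analysis of collagen-I secretion and fibril assembly as two
separable processes. Fibroblasts export procollagen-I (PCI) continuously,
but assembling it into D-periodic extracellular fibrils is a distinct,
cell-controlled step; telling the two apart requires several independent
quantifications, each of which this package implements as a tested,
reusable pipeline:

* **`fibrilkit.silac`** — protein half-lives from pulse-SILAC peptide
  tables. After a heavy-lysine pulse of length *p* with cell doubling time
  *d*, the heavy/light intensity ratio HL of a protein's peptides gives

  ```
  k = ln(HL + 1)/p − ln(2)/d        t½ = ln(2)/k
  ```

  with division-dilution correction, evidence filtering (≥3 peptides, ≥1
  heavy, ≥2 replicates) and censoring when decay cannot be distinguished
  from dilution (HL ≤ 2^(p/d) − 1).
* **`fibrilkit.photoswitch`** — kinetics from green→red photoswitchable
  fluorophore (Dendra2-type) time-lapse traces: normalization, log-linear
  exponential decay fits with bootstrap CIs, periodogram rhythm detection
  for the synthesis channel, and the nucleation/secretion loss-rate ratio.
* **`fibrilkit.morphometry`** — AFM height-map flattening, fibril D-period
  estimation (autocorrelation + peak-spacing spread), skeleton-based
  fibril segmentation with sub-pixel length measurement, per-cell counts,
  and unpaired group comparisons.
* **`fibrilkit.secretion`** — nanoluciferase calibration curves,
  secretion rates in molecules/cell/h (exact Avogadro constant), pool
  turnover times, compartment partitions, and a well-mixed (CSTR) washout
  model for perfused-bioreactor cultures.
* **`fibrilkit.simulate`** — synthetic-data generators for all of the
  above with ground-truth records, used throughout the test suite for
  parameter-recovery validation.

Intended users: cell biologists and proteomics/imaging analysts
quantifying secretion and assembly of fibrillar collagens (or any secreted
protein with similar assay designs).

## Worked example

Estimate half-lives from a simulated 200-protein SILAC experiment (48 h
pulse, 72 h doubling, 20% intensity CV) and ask what light-peptide
fraction a 69.8 h half-life implies:

```python
from fibrilkit import silac, simulate

cfg = simulate.SilacSimConfig(n_proteins=200, intensity_cv=0.2, seed=1)
table, truth = simulate.gen_silac_table(cfg)   # 6472 peptide observations
estimates, summary = silac.run_turnover(table)
print(summary)
# {'n_input_proteins': 200, 'n_retained': 200, 'n_rejected': 0,
#  'n_censored': 0, 't_half_median_h': 46.526, 't_half_q25_h': 31.735,
#  't_half_q75_h': 58.78, 'pulse_h': 48.0, 'doubling_h': 72.0,
#  'ratio_method': 'intensity-sum'}

f, hl = silac.implied_light_fraction(69.8)
print(f"69.8 h -> light fraction {f:.4f} (HL = {hl:.4f})")
# 69.8 h -> light fraction 0.3911 (HL = 1.5568)
```

The summary says all 200 simulated proteins passed the evidence filter,
none were censored, and the estimated half-life distribution centres on
~46.5 h (the generator's true median is 46 h). The second call inverts the
decay equations: a protein with a 69.8 h half-life should show ~39.1% of
its peptides still light after the 48 h pulse — the kind of cross-check
that ties a measured light/heavy split to a claimed turnover time.

The same pipelines are available from the shell:

```
fibrilkit simulate silac --seed 3 --out sim/
fibrilkit turnover --in sim/peptides.tsv --out estimates.tsv
fibrilkit simulate image --seed 5 --out img/
fibrilkit fibrils count --in img/fibrils.tif --cells img/cells.tif
fibrilkit secretion flow --rate 1.0 --volume 2.0 --flow 0.05 --duration 72
```

## Documentation

`docs/methods.md` describes the models, their assumptions, the numerical
choices, what the synthetic data do and do not emulate, and known
limitations.
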