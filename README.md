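# sedsource

Point-source identification in harbour sediment monitoring data.

## The problem

Industrial harbours accumulate heavy metals, PAHs and hydrocarbons in bottom
sediments from two kinds of origin: *nonpoint* (diffuse) contamination spread
over the whole basin, and *point* sources — terminals, spills, discharges —
that leave a localized chemical fingerprint at a few sampling positions.
Monitoring campaigns produce a positions × chemicals concentration matrix;
the question is which positions are near a point source, which positions
share the *same* source, and which of them pose the greatest ecological risk.
`sedsource` implements a five-stage screening procedure for exactly this,
aimed at environmental chemists and port-authority consultants working from
tabular campaign data in Python.

## The method

Concentrations (mg/kg dry weight) are first expressed as hazard quotients
HQ = C / LCL against regulatory sediment limits, then:

* **Step 0 — chemical PCA.** Covariance-matrix PCA with chemicals as
  variables; the share of each chemical in the total variance
  (diag Σ / tr Σ) exposes a dominant diffuse pollutant, which is removed and
  the PCA re-run to reveal the secondary structure.
* **Step 1 — sample PCA.** The same decomposition with *positions* as the
  variables. Positions whose coordinate `loading·√λ` on the retained
  components (scree-selected, at least two) lies far from the robust centre
  are outliers: candidate point sources.
* **Step 2 — MAD screening.** For each chemical, every position is scored
  with `On(x) = |x − median| / MAD`; positions exceeding a cutoff `n`
  (default 4) above the median on some chemical are flagged, and the
  offending chemicals identify the discharge type.
* **Step 3 — ratio matching.** Each flagged position's fingerprint is the
  strictly-upper triangle of its m×m pairwise concentration-ratio matrix —
  invariant under dilution. Two fingerprints are compared elementwise; a
  quotient is a match if it falls within the 0.90–1.10 band, and positions
  linked by ≥ 90 % matching ratios cluster as one source. Isolated
  discharges come back as singleton clusters.
* **Step 5 — risk ranking.** Concentrations are re-normalised by sediment
  PNECs (explicit value, `Kp · PNEC_water`, or an assessment-factor
  derivation `min(endpoint/AF)`), and the sample-PCA outlier machinery on
  the risk-quotient matrix ranks positions by ecological risk.

(Step 4 of the workflow — attributing clusters to terminals on a harbour
map — is a human/GIS task and out of scope.)

A first-class synthetic generator (`SyntheticScenario`, `generate`) produces
harbour-like datasets with known ground truth — bounded diffuse background,
a dominant pollutant with a chosen variance share, planted sources under
dilution and noise, replicates, detection limits — so every stage has a
recoverable target.

## Worked example

```bash
python examples/01_full_pipeline.py
```

prints (abridged):

```
Step 0 - top variance weights (% of overall HQ variance):
zinc                   72.66
hydrocarbons_c_gt12     8.79
  -> dominant nonpoint pollutant eliminated: zinc

Step 2 - MAD screen at On >= 4.0:
  P63: sum_pah, pyrene, chrysene, indeno_123cd_pyrene
  P68: hydrocarbons_c_gt12, fluoranthene, pyrene, benzo_a_pyrene
  ...
  P64: cadmium, lead, mercury
  P65: cadmium, lead, mercury

Step 3 - ratio-matching clusters (per hypothesised chemical subset):
  step2_P68: [['P66', 'P67', 'P68']]
  step2_P64: [['P64', 'P65']]

Planted truth: {'pah_spill': ['P63'], 'cadmium_discharge': ['P64', 'P65'],
                'hc_terminal': ['P66', 'P67', 'P68']}
Recovery: sensitivity=1.00, false positives=0, cluster agreement=1.0
```

Zinc is recognised as the diffuse pollutant carrying ~three quarters of the
overall variance and removed; the MAD screen flags exactly the six planted
source positions with their signature chemicals; ratio matching groups the
three hydrocarbon-terminal positions and the two cadmium positions into one
cluster each, while the single-position PAH spill stays a singleton. The
other `examples/` scripts demonstrate each capability in isolation (MAD
arithmetic, ratio fingerprints, PNEC resolution, CSV ingestion).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the default synthetic scenario from the seed, runs the entire
pipeline from scratch (variance weights, dominant elimination, both outlier
routes, ratio clustering, PNEC risk ranking), prints the stage summaries and
recovery metrics, and writes the result JSON to `--out`.

## Layout

- `src/sedsource/data.py` — data model, CSV I/O, aliasing, aggregation, HQ
- `src/sedsource/pca.py` — covariance PCA (both orientations), scree, outlier ranking
- `src/sedsource/outliers.py` — MAD/On statistics and the source screen
- `src/sedsource/ratios.py` — ratio fingerprints and band clustering
- `src/sedsource/risk.py` — PNEC derivation and risk ranking
- `src/sedsource/synthetic.py` — scenario generator and recovery scoring
- `src/sedsource/study_design.py` — campaign bookkeeping template
- `src/sedsource/pipeline.py` — end-to-end orchestration and report bundles
- `docs/methods.md` — the model, parameter choices and known limitations
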