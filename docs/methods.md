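# Methods

## Scope and data model

`sedsource` screens a positions × chemicals sediment concentration matrix for
point pollution sources. A *position* is a fixed sampling location; repeat
visits across campaigns and aliased station names (e.g. `F2`/`F2bis`)
collapse onto one row. Replicate samples are combined by the mean per
position per chemical (median available); the mean matches the
variance-covariance conventions of the PCA stages. Below-detection-limit
readings are stored with their detection limit and a flag: they enter the
PCA/MAD stages at half the detection limit (the usual chemometric
substitution) but are masked in ratio fingerprints, because a ratio built on
a censored value is not source evidence. Unmeasured cells stay missing and
are handled by pairwise-complete covariance; nothing is imputed. Units are
mg/kg dry weight; readers convert declared µg/kg columns.

## Normalisations

Two scalings of the same matrix drive different questions:

* **hazard quotients** HQ = C / LCL (regulatory sediment limit) make
  chemicals with very different natural abundances comparable and are the
  input to all source-identification stages;
* **risk quotients** RQ = C / PNEC_sediment weight chemicals by toxicity
  rather than by regulation and drive the final risk ranking. PNEC_sediment
  resolves in order: explicit value; equilibrium partitioning
  `Kp [L/kg] × PNEC_water [mg/L]`; `Kp ×` an assessment-factor derivation
  `min(endpoint / AF)` from acute aquatic endpoints. The minimum-over-
  endpoints AF rule is the standard technical-guidance convention; the
  resolution path per chemical is recorded in an audit table. Chemicals with
  no resolvable PNEC (e.g. a summed-PAH aggregate) are dropped from the risk
  matrix with a warning by default.

## PCA

PCA is always on the **variance-covariance** matrix of mean-centered,
unscaled variables: the matrices are already dimensionless quotients and the
absolute spread is the signal. A correlation mode exists for sensitivity
analysis only. Eigenvector signs follow the convention that each loading
vector's largest-magnitude element is positive. With missing cells the
covariance is pairwise-complete, which can produce slightly negative trailing
eigenvalues; they are clipped to zero when explained fractions are formed.

Two orientations are used. With chemicals as variables, the per-chemical
variance weights (diag Σ / tr Σ, reported as percentages) expose a dominant
diffuse pollutant; removing its column and re-running the PCA reveals the
secondary structure. With positions as variables, each position has a
coordinate `loading · √λ` per component; positions far from the robust centre
of that coordinate space are outliers. Because eigen-analysis is scale-free
in the component count, a deterministic scree rule replaces by-eye reading:
retain the smallest k with cumulative explained fraction ≥ 0.95
(configurable; a largest-relative-drop alternative is provided). The outlier
ranking defaults to `max(2, k)` components — the leading two components are
always inspected even when the first alone passes the scree threshold,
matching how score plots are actually read.

Outlier selection in coordinate space reuses the MAD machinery: a position is
selected when its On score on some retained component reaches the same
cutoff used by the MAD screen (default 4). Components whose eigenvalue is
numerically zero relative to the leading one, and coordinate deviations at
rounding level, are ignored — ratios of floating-point noise are not
outliers. A `per_pc_extreme` mode instead picks the single most extreme
position per component, the literal by-eye reading.

## MAD screening

For each chemical the across-position distribution is summarised by median
and MAD (no 1.4826 consistency constant — cutoffs are in raw MAD units), and
`On(x) = |x − median| / MAD` is computed for every position, scoring each
observation against the full distribution including itself. A (position,
chemical) cell is *flagged* when On ≥ cutoff, the value lies **above** the
column median and the cell is not censored: a point source adds
contamination, so low-side exceedances (typically detection-limit
substitution artefacts) are reported in the score grid but never as source
evidence; a symmetric mode is available. Constant columns yield On = 0 at the
median and an infinity sentinel elsewhere and are listed as degenerate.
Flagged positions are ranked by their maximum On over flagged chemicals,
ties broken by the number of offending chemicals, then by position id.
Raising the cutoff can only shrink the list, so screens at 4 and 5 are
nested. No multiple-testing correction is applied across the n×m grid; the
procedure is a screen, not a test.

## Ratio matching

A sample's fingerprint is the strictly-upper triangle of its m×m pairwise
concentration-ratio matrix (m(m−1)/2 entries; 378 for m = 28). Ratios are
dilution-invariant, so samples polluted by one source keep their fingerprint
as absolute levels vary. Two fingerprints are compared by the elementwise
quotient over jointly unmasked pairs; a quotient matches when it lies in the
acceptance band. The printed band 0.90–1.10 is not reciprocal-symmetric
(1/0.9 ≈ 1.111), so the default test is the symmetrised
`min(r, 1/r) ≥ 0.90` ⟺ `|log r| ≤ |log 0.90|`, making comparison
order-independent; a literal-interval mode is kept for fidelity. Positions
are linked when ≥ 90 % (configurable) of their compared quotients match *and*
at least three ratios could be compared — agreement on one or two surviving
ratios is too little evidence when the rest of a subset is masked. Clusters
are connected components of the link graph (average-linkage hierarchical
clustering on 1 − in-band-fraction is offered as an alternative); unlinked
positions are singletons.

Cluster runs are subset-specific, not one global partition: the pipeline
clusters the Step-2 flagged positions (never recomputing the outlier set)
once per chemical subset — the two class families (heavy metals;
PAH/hydrocarbons) and, for each flagged position, the subset of its
offending chemicals. A subset run includes only positions flagged for at
least one chemical of that subset; positions whose exceedances lie elsewhere
are pure background in those ratios and would contribute only chance links.
Overlapping clusters across runs are expected and meaningful (a position may
carry two sources' chemistries).

## Synthetic scenarios

The generator states a world in which every stage has a recoverable target.
Per position p, chemical c, replicate s:

    conc = LCL_c · ( B_pc + Σ_sources 1[p ∈ source] · sig_c · strength · d_s )
           · exp(σ_n Z − σ_n²/2)

* **Background** B_pc is bounded: ordinary chemicals follow a log-uniform
  field `median · exp(σ T)`, T ~ U(−1.6, 1.6), with background CV 0.10; the
  dominant pollutant follows a uniform envelope `median_d (1 + w U)`,
  U ~ U(−1, 1). Boundedness is deliberate: On is affine-invariant, so its
  false-alarm rate depends only on tail shape, and *any* unbounded background
  (even Gaussian) guarantees several On ≥ 4 exceedances in a 68 × 28 grid.
  The bounded field encodes the screen's working premise — only point
  sources exceed the cutoff. Real sediments with heavy-tailed natural
  variability will produce more false alarms than these tests show; that is
  a property of the method, not of the implementation.
* **Dominant share.** The envelope half-width w is solved in closed form so
  the dominant chemical carries a requested share (default 76.3 %) of the
  expected overall HQ variance, *including* the variance the planted sources
  add (dilution moments included, measurement noise neglected — at CV 0.02
  its contribution is two orders below the rest). Defaults put the dominant
  median at HQ 8, i.e. widespread exceedance, consistent with a harbour whose
  diffuse pollution dominates the dataset.
* **Sources.** Three archetypes: a single-position PAH spill, a two-position
  cadmium discharge, a three-position heavy-hydrocarbon terminal. Signature
  levels sit ≥ ~8× above the background median. This is the sizing the
  acceptance band itself presumes: a quotient of two ratio fingerprints
  stacks four background perturbations of relative size (bg·CV)/signature,
  so staying inside ±10 % with margin requires each term of order a few
  percent. Dilution is U(0.5, 1.5) per sample and multiplies the whole
  signature, leaving fingerprints invariant.
* **Noise and censoring.** Multiplicative lognormal noise, CV 0.02 per cell
  (within the ≤ 5 % regime the recovery properties assume; three replicates
  are averaged per position). Detection limits sit at the background's 2 %
  quantile; the dominant is never censored.
* Same seed ⇒ byte-identical output; scenarios round-trip through
  YAML/JSON.

Recovery is scored as sensitivity/specificity of the flagged set against the
planted positions, and as the adjusted Rand index between planted labels and
multi-position cluster membership, per source, over the cluster run whose
chemical subset best matches that source's signature. Singleton sources are
checked to come back unclustered.

## Numerical and design choices

* Scree thresholds, cutoffs, bands and link thresholds are configuration,
  not constants; defaults are 0.95 / 4.0 / (0.90, 1.10) / 0.90.
* `On` cutoffs compare raw MAD units; switching to 1.4826-scaled MADs would
  rescale every cutoff by the same factor and change nothing else.
* Eigen-decomposition uses `numpy.linalg.eigh` on the explicitly formed
  covariance; tests verify equivalence against an independent brute-force
  oracle to 1e-10 and trace conservation to 1e-9.
* Degenerate inputs: constant matrices are rejected (zero covariance);
  constant chemical columns are reported as degenerate, not dropped;
  positions with fewer than two valid chemicals in a subset cannot form a
  fingerprint and stay singletons; empty eigen-spectra, nonpositive cutoffs
  and inverted bands raise immediately.
* The pipeline is deterministic for a fixed seed and config; the manifest
  embeds the config snapshot, a hash, and library versions.

## Known limitations

* The MAD screen's false-positive behaviour on heavy-tailed natural
  backgrounds is untested by construction (see above); a green synthetic
  suite establishes correctness of the machinery and recoverability in the
  stated world, not field performance.
* Pairwise-complete covariance is an approximation under missingness; with
  the fourth-campaign pattern (extra PAHs measured only late) variable pairs
  rest on different sample sets.
* The risk-stage PCA inherits the component-selection sensitivity: with two
  retained components, sources orthogonal to the leading structure can be
  missed. The MAD screen applied to the risk matrix is the robust companion
  and always covers the PCA selection in the synthetic world.
* Ratio matching assumes one source dominates a contaminated sample; mixed
  fingerprints at one position dilute the in-band fraction and tend to break
  clusters apart rather than merge them.
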