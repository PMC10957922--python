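# spatialsr

Threshold-free quantification of spatial relationships (SRs) in
multiplex-immunofluorescence (mIF) cell maps, for tumor-microenvironment
biomarker studies.

An mIF slide reduces to a table of nucleus coordinates (μm) and cell
phenotypes — here a seven-class vocabulary: cancer, CD8⁺ T, FoxP3⁺ T,
T-helper, B cell, macrophage, and *negative* (negative for every panel
marker). Classical summaries of such maps — immune-cell densities per
tissue compartment, exclusion ratios — discard the cell-to-cell proximity
structure that governs immune interactions. `spatialsr` instead models,
for every ordered pair of cell types, the distribution of
first-nearest-neighbor (1-NN) distances: for each *reference* cell, the
distance to its closest *target*-type cell. The statistic is asymmetric
(CD8→B cell ≠ B cell→CD8).

## Model

Each sample's smoothed, unit-area 1-NN density is approximated by a
Weibull density

$$f(x; a, b) = \frac{a}{b}\left(\frac{x}{b}\right)^{a-1} e^{-(x/b)^a},$$

with shape $a$ (distribution form: packed, clustered, repulsed regimes)
and scale $b$ (μm; distribution width). Because the parameters must be
positive, they are re-parameterized through scaled logistic links
$a = 10/(1+e^{-A})$, $b = 500/(1+e^{-B})$ with unconstrained $A, B$. A
cohort of samples is fitted jointly by a nonlinear mixed-effects model:
fixed effects $(A, B)$ plus per-sample Gaussian random effects with
diagonal covariance, estimated by a Laplace-approximated marginal
likelihood with an REML-style correction. The two numbers $(a, b)$
summarize an SR without choosing a distance threshold — unlike the
G-function summary $\text{G-AUC-}T$ (area under the 1-NN ECDF up to
$T$ μm), which is also provided for comparison and whose value depends
strongly on $T$.

Useful closed forms: the median 1-NN distance is
$b(\ln 2)^{1/a}$; under complete spatial randomness of the target type
at intensity $\lambda$, the cross 1-NN distances are exactly Weibull
with $a = 2$, $b = (\pi\lambda)^{-1/2}$ — the package's main built-in
oracle.

Supporting machinery: DBSCAN tissue-focus splitting (ε = 300 μm,
minPts = 50), tumor/stroma segmentation by comparing max-normalized
Gaussian kernel intensity surfaces of cancer vs. negative cells
(likelihood cross-validated bandwidth), compartment areas at the 0.1
normalized-intensity threshold, a 150-μm distal-stroma trim, compartment
densities and exclusion ratios, and a response-association battery
(Welch t-tests with Benjamini–Hochberg FDR per metric family,
Mann–Whitney median comparisons, logistic-regression ROC with stratified
bootstrap CIs, paired-bootstrap AUC comparisons, leave-one-out deviance).
A seed-reproducible synthetic-cohort generator (Thomas-process cancer
nests, proximity-thinned immune populations with a configurable
responder/non-responder effect) makes the whole stack testable without
patient data.

## Worked example

Simulate a small two-arm cohort (3 responders, 3 non-responders), fit
the CD8⁺ T cell → cancer cell SR, and segment one slide:

```sh
$ spatialsr simulate --out-dir cohort --seed 7 --n-samples 3
wrote 6 slide(s) and labels.csv to cohort

$ python -c "
import pandas as pd, glob
pd.concat([pd.read_csv(p, sep='\t') for p in sorted(glob.glob('cohort/[RN]*.tsv'))]).to_csv('all_cells.tsv', sep='\t', index=False)"

$ spatialsr fit --cells all_cells.tsv --pairs cd8_t:cancer --out fits.json --per-sample params.tsv
cd8_t->cancer: level=none converged=True shape=1.209 scale=37.84

$ cat params.tsv
sr	sample_id	shape	scale
cd8_t->cancer	N01	0.923372247259161	97.87654504281863
cd8_t->cancer	N02	1.1837200098261906	63.89251614058967
cd8_t->cancer	N03	1.1228240802936875	135.56360153811772
cd8_t->cancer	R01	1.2945778637362642	13.234128853615635
cd8_t->cancer	R02	1.1799848693976847	16.756983063713655
cd8_t->cancer	R03	1.6561340111820493	10.956589474713919
```

The cohort fit converged on all samples (`level=none`: no cell-count
filtering was needed) with population shape 1.21 and scale 37.8 μm. The
per-sample scales separate the groups: responders (R01–R03) have scales
of 11–17 μm — CD8⁺ T cells sit close to their nearest cancer cell —
while non-responders (N01–N03) have scales of 64–136 μm, the simulated
exclusion pattern. Segmentation of one slide:

```sh
$ spatialsr segment --cells cohort/R01.tsv --out R01_seg.tsv --areas R01_areas.tsv
wrote R01_seg.tsv and R01_areas.tsv
$ cat R01_areas.tsv
sample_id	tumor_area	stroma_area	total_area
R01	236842.2322741754	842039.092465064	1078881.3247392394
```

i.e. ~0.24 mm² of tumor compartment in ~1.08 mm² of tissue. The
`pipeline` subcommand chains every step (segment → 1-NN → fit → metrics
→ associate) and writes a manifest in which every (sample × cell-type
pair) unit terminates as `fit`, `filtered-at-level-L`, `rejected`, or
`errored`.

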