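# Methods

## Screening risk model

The model follows the standard three-route residential/agricultural soil
exposure framework. For compound *i* with oral/inhalation reference doses
`RfD_o`, `RfD_i` (mg·kg⁻¹·day⁻¹), dermal absorption fraction `ABS`, and a
particulate emission factor `PEF` (or volatilization factor `VF_s` for
volatile compounds, selected by a per-compound flag; default is `PEF`,
since all 31 analytes are semi- or low-volatile), the noncarcinogenic soil
screening level is

    SSL_nc = THQ·BW_c·AT_n / ( EF_r·ED_c·[ IRS_c/(RfD_o·10⁶)
             + SA·AF·ABS/(RfD_o·10⁶) + IRA_c/(RfD_i·PEF) ] )

with averaging time `AT_n = ED_c × 365` days. Defaults describe a child
farmer: THQ 1, BW 15 kg, EF 250 day/yr, ED 25 yr, IRS 100 mg/day, SA
3470 cm²/day, AF 0.12 mg/cm², IRA 20 m³/day. The dermal term divides by
the oral reference dose with no gastrointestinal-absorption adjustment —
a deliberate fidelity choice to the screening framework being
reimplemented rather than to later refinements of it. The carcinogenic
level uses cancer slope factors and age-adjusted intake factors:

    SSL_c = TR·AT_c / ( EF_r·[ IFS_adj·CSF_o/10⁶
            + SFS_adj·ABS·CSF_o/10⁶ + InhF_adj·CSF_i/PEF ] )

with TR 10⁻⁶, AT_c 25 550 days, IFS 100, SFS 361, InhF 11. The combined
effect basis takes the per-compound minimum of the two levels
(conservative); separate bases remain available. Hazard quotients convert
units in exactly one place (`HQ = (PEC μg/kg / 1000) / SSL mg/kg`); the
hazard index is the plain sum (additivity, no interaction or synergy),
and contributions are `p_i = HQ_i / HI`, defined only for `HI > 0`.
Contributions are deliberately oriented as compound-share-of-index — the
quantity whose closed vector sums to one and feeds the compositional
analysis.

## Censored concentrations

Values below the detection limit are stored flagged and replaced by DL/2
before any summation or statistical step (the conventional substitution
for left-censored environmental data; no multiplicative or EM imputation
is attempted). Substitution is idempotent. The per-compound MAD is
reported unscaled (no 1.4826 consistency factor): a column with most
observations at one substituted DL/2 value then correctly shows MAD = 0,
matching the behaviour of the survey summary the fixtures emulate.

## Aitchison geometry

Compositions are strictly positive, closure-normalized vectors; zeros
must be resolved upstream (half-DL), never clipped silently. The clr
transform is `ln(x_i/g(x))`; ilr coordinates use the Helmert-type balance
basis `z_j = sqrt(j/(j+1))·ln(g(x_1..x_j)/x_{j+1})`, whose contrast
matrix `psi` satisfies `psi·psiᵀ = I` and row sums zero. All downstream
results reported in clr space (PCA loadings, distances, total variance)
are invariant to the particular orthonormal basis; coordinate-level ilr
output is basis-dependent and the basis matrix is exposed for that
reason. The variation matrix uses the unbiased (n−1) variance estimator,
consistent with `np.cov` defaults, so biplot link lengths and
variation-matrix entries agree exactly on rank-2 data. Ternary
coordinates place part 1 at (0,0), part 2 at (1,0), part 3 at
(1/2, √3/2); grid centering applies the same perturbation to gridline
compositions as to the data.

## Ordination

PCA runs on ilr coordinates. Robust location/scatter come from the
minimum covariance determinant (scikit-learn `MinCovDet`, support
fraction 0.75, seeded and deterministic); the classical path uses the
sample mean/covariance and reproduces a direct eigendecomposition of the
ilr covariance. Loadings are back-transformed to clr via `psiᵀ·V`;
scores stay in ilr (distances preserved). Component signs are fixed by
making each loading's largest-magnitude clr entry positive. The
covariance biplot scales rays by the square roots of the eigenvalues, so
squared inter-vertex links estimate log-ratio variances; representative
subcomposition selection picks, per compound family, the part with the
longest two-component clr ray. PCoA double-centres `−D²/2`,
eigendecomposes, drops negative eigenvalues with a warning (they are
numerically tiny for Aitchison input, which is exactly
Euclidean-embeddable) and Gower-scales eigenvectors by `sqrt(λ)`, so
coordinate distances reproduce the input distances; scikit-bio's
implementation serves as an independent oracle in the tests.

## Fuzzy c-means

Standard alternating updates (`u_ik = 1/Σ_j (d_ik/d_jk)^{2/(m−1)}`,
prototypes as `u^m`-weighted means) on ilr coordinates, with k-means++
seeding from the given seed, fuzzifier m = 2, tolerance 1e-6 on the
maximum prototype shift, 300 iterations maximum. A point coinciding with
a prototype receives an indicator membership (split equally over
coincident prototypes). The objective `J_m = ΣΣ u^m d²` is recorded per
iteration and is non-increasing. Cluster identities are canonicalized by
descending hard-label size. Cluster-count assessment reports Bezdek's
partition coefficient and the silhouette of the hard labels side by
side without auto-deciding, since the two criteria can disagree on real
data. Cluster profiles are closed geometric means of centred member
compositions — membership-weighted by default — with parts above 1/D
flagged as enriched relative to the overall centre.

## Synthetic surveys

The generator emulates a 100-site, 31-compound survey. An embedded
published summary table (per-compound MIN/MED/MAX/MAD, censoring rates,
median hazard quotients and their percent shares of the median hazard
index) anchors all fixtures:

* **Toxicity registry** — synthetic, obtained by inverting the screening
  equations so each compound's combined-basis SSL equals
  `(MED/1000)/MED_HQ`; screening the median concentration column then
  reproduces the median hazard quotients exactly, and the compound
  ranking (BaP ≫ BbF > BaA …) is preserved. This registry is an
  emulation for testing, not a measured set of toxicity criteria.
  Carcinogen flags cover the seven classic carcinogenic PAHs; their
  noncarcinogenic SSL is set 10× the carcinogenic one so the combined
  minimum selects the cancer route. ABS is 0.13 for PAHs and 0.10
  otherwise; PEF is 1.316×10⁹ m³/kg throughout.
* **Detection limits** — not published per compound; each compound's
  smallest observed concentration serves as a DL surrogate (an explicit
  assumption).
* **Archetypes** — the PAH-dominated mean is the closed median-HQ
  composition; the DDT-dominated mean multiplies the six DDT-family
  parts by 200 and re-closes; the mixed organochlorine mean multiplies
  PCBs, HCH isomers and the chlorobenzenes by 100. Mixing weights are
  0.4/0.3/0.3. Within-archetype variation is logistic-normal with
  σ = 0.3 per ilr coordinate — fixed a priori so that the archetype
  means sit ≥ 4× the rms within-archetype spread apart (the separation
  asserted at construction; ratio ≈ 7 in practice) while per-cluster
  geometric means of ~100 draws still estimate the archetype means to
  within Aitchison distance 0.25 (expected error ≈ sqrt(30σ²/n_k) ≈
  0.17).
* **Hazard indices** — log-normal with median 0.214 (the anchor-derived
  median of the reference summary) and log-sd 0.9375, putting ≈ 5% of
  sites above HI = 1, echoing the sparse high-risk highlighting of the
  emulated survey.
* **Concentrations** — the risk model inverted:
  `PEC_i = p_i·HI·SSL_i·1000` μg/kg, then left-censored at the DL with
  DL/2 substitution. Without censoring the round trip through
  `evaluate_site` recovers the drawn contributions to 1e-10.

What the generator does **not** emulate: spatial autocorrelation among
sites, correlated analytical error across compounds, heavy-tailed
single-site anomalies beyond the log-normal HI, or the real survey's
actual toxicity criteria and cluster memberships. Tests passing on this
generator demonstrate that the pipeline recovers a known latent
structure under its own model assumptions — not that any particular
field dataset contains three clusters.

## Problem sizes and numerical choices

The recovery study uses 20 replicate surveys of 100 sites × 31 compounds,
chosen as the natural scale of the emulated campaign; each replicate
takes well under a second. Closure tolerance is 1e-10; compositional
round-trip accuracy is required at 1e-12, metric identities at 1e-10,
variance bookkeeping and PCoA distance reconstruction at 1e-8 (pairwise
distances are computed via `scipy.spatial.distance.pdist` rather than
the expanded inner-product formula, which loses ~1e-7 to cancellation).
MCD estimation needs n > D; with 100 sites and 30 ilr coordinates the
0.75 support fraction leaves 75 observations for the determinant search.
Ties in the FCM size-canonicalization are broken by first cluster index;
degenerate inputs (single-part compositions, empty vectors, zero hazard
index, asymmetric distance matrices) raise typed errors rather than
propagating NaNs.

## Known limitations

* Additive hazard model only: no compound interactions, bioaccessibility
  or dietary pathways.
* DL/2 substitution biases heavily-censored minor parts toward a common
  value; the contribution representation mitigates but does not remove
  this, and profile estimates for boosted archetypes show a visible
  censoring bias in their minor parts.
* The percent-share reconstruction of the reference summary is exact
  only up to the anchor-derived normalization constant; the underlying
  per-site data are not available.
* Explained-variance figures and cluster memberships of the original
  field survey are not reproducible from the published summary; the
  synthetic study checks structural recovery instead.
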