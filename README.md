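# floodrisk

Screening human-health risk assessment of persistent organic pollutants
(POPs) in floodplain soils, with a compositional-data exploration of the
resulting risk profiles.

Floodplain soils accumulate PAHs, PCBs and organochlorine pesticides from
atmospheric deposition, industry and legacy agriculture. For an exposure
scenario (soil ingestion, dermal contact, inhalation of soil-derived
particles), each measured concentration `PEC_i` (μg/kg) is screened against
a risk-based soil screening level `SSL_i` (mg/kg) derived from exposure and
toxicity parameters. The per-compound hazard quotient, site hazard index
and contribution shares are

```
HQ_i = PEC_i / SSL_i        HI = Σ_i HQ_i        p_i = HQ_i / HI
```

with `HI < 1` meaning no adverse effect is expected. The vector
`p = (p_1, …, p_D)` sums to one: it is *compositional*, so the package
analyses it in the Aitchison geometry of the simplex — centred (clr) and
isometric (ilr) log-ratio transforms, robust principal component analysis
with compositional biplots, principal coordinate analysis of Aitchison
distances, fuzzy c-means clustering and ternary diagrams of representative
subcompositions. A synthetic survey generator reproduces the statistical
structure of a ~100-site, 31-compound field campaign (three latent
pollution archetypes, log-normal hazard indices, left-censored
concentrations) so the whole pipeline is testable without field data.

Intended users: environmental scientists and risk assessors screening
multi-compound soil surveys, and anyone needing a tested reference
implementation of log-ratio ordination and fuzzy clustering for
contribution-type data.

## Worked example

Screen the embedded survey's median concentration column against the
synthetic toxicity registry (derived so that its screening levels are
consistent with that summary):

```python
import numpy as np
from floodrisk import risk, synthetic

s = synthetic.reference_survey_summary()      # 31 compounds
tox = synthetic.toxicity_registry()
res = risk.evaluate_site(s["med"].to_numpy(), tox, s.index, "combined")
print(round(res.hi, 4))                       # 0.2124  (HI < 1: acceptable)
for i in np.argsort(res.contributions)[::-1][:3]:
    print(s.index[i], round(res.hq[i], 6),
          f"{100 * res.contributions[i]:.2f}%")
# BaP 0.152897 71.98%
# BbF 0.018431 8.68%
# BaA 0.012255 5.77%
```

Benzo(a)pyrene alone carries ~72% of the median hazard — exactly the
dominance that motivates the log-ratio treatment: in raw shares every
site collapses onto the BaP vertex of a ternary diagram, while the
clr/ilr view resolves the PAH / DDT / mixed-organochlorine contrasts.

The full pipeline (synthetic survey → half-DL substitution → screening →
robust PCA → PCoA → fuzzy c-means → profiles) runs from the shell:

```sh
floodrisk run --seed 7 --outdir out/
# analysed 100 sites x 31 compounds; 6 site(s) with HI > 1; outputs in out/
```

`out/` then holds the summary, hazard and contribution tables, clr
loadings and scores (first two robust components explained 79% and 13%
of the variance for this seed), PCoA coordinates, fuzzy memberships,
cluster profiles, ternary coordinates and a `report.json` echoing the
configuration; sites with HI > 1 are flagged in every table. Reruns with
the same seed are byte-identical.

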