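"""Screening human-health risk model for soil contaminants.

The screening logic follows the standard USEPA residential/agricultural
soil pathway model for three direct exposure routes — incidental soil
ingestion, dermal contact and inhalation of soil-derived particles. For
each compound a risk-based soil screening level (SSL, mg/kg) is derived by
combining exposure assumptions with toxicity criteria:

* noncarcinogenic SSL — the soil concentration at which the exposure dose
  equals the reference dose times a target hazard quotient (THQ):

  ``SSL = THQ·BW_c·AT_n / (EF_r·ED_c·[IRS_c/(RfD_o·1e6)
  + SA·AF·ABS/(RfD_o·1e6) + IRA_c/(RfD_i·VF_or_PEF)])``

* carcinogenic SSL — the concentration posing a target lifetime excess
  cancer risk (TR), with age-adjusted intake factors and cancer slope
  factors (CSF):

  ``SSL = TR·AT_c / (EF_r·[IFS_adj·CSF_o/1e6 + SFS_adj·ABS·CSF_o/1e6
  + InhF_adj·CSF_i/VF_or_PEF])``

Measured concentrations (PEC, μg/kg) are screened against the SSL through
the hazard quotient ``HQ = PEC/SSL`` (after μg→mg conversion); quotients
add up to the site hazard index ``HI = Σ HQ`` under the additive
no-interaction assumption, and ``HI < 1`` indicates no adverse effect is
expected under the scenario. The closed vector ``p_i = HQ_i / HI`` gives
each compound's relative contribution to the site's hazard — the
compositional object the downstream multivariate analysis works on.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "load_toxicity",
    "load_scenarios",
    "ToxicityProfile",
    "NoncarcScenario",
    "CarcScenario",
    "EffectBasis",
    "HazardResult",
    "ssl_noncarcinogenic",
    "ssl_carcinogenic",
    "screening_level",
    "hazard_quotient",
    "hazard_index",
    "risk_contributions",
    "evaluate_site",
    "evaluate_table",
]

_MG_PER_KG = 1e6  # unit-conversion constant in the intake terms


@dataclass(frozen=True)
class ToxicityProfile:
    """Chemical-specific toxicity and transfer parameters.

    Reference doses (RfD) are in mg·kg⁻¹·day⁻¹; cancer slope factors (CSF)
    in (mg·kg⁻¹·day⁻¹)⁻¹; ``abs_skin`` is the unitless dermal absorption
    fraction; ``vf_s``/``pef`` (m³/kg) translate a soil concentration into
    an air concentration for the inhalation route, chosen by
    ``volatile_flag``.
    """

    rfd_o: float | None = None
    rfd_i: float | None = None
    csf_o: float | None = None
    csf_i: float | None = None
    abs_skin: float = 0.1
    vf_s: float | None = None
    pef: float | None = 1.316e9
    volatile_flag: bool = False

    def __post_init__(self):
        for name in ("rfd_o", "rfd_i", "csf_o", "csf_i", "vf_s", "pef"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when present")
        if not (0 < self.abs_skin <= 1):
            raise ValueError("abs_skin must lie in (0, 1]")
        if self.vf_s is None and self.pef is None:
            raise ValueError("need at least one of vf_s / pef")

    @property
    def vf_or_pef(self) -> float:
        if self.volatile_flag:
            if self.vf_s is None:
                raise ValueError("volatile_flag set but vf_s missing")
            return self.vf_s
        if self.pef is None:
            raise ValueError("pef missing for non-volatile compound")
        return self.pef


@dataclass(frozen=True)
class NoncarcScenario:
    """Exposure parameters for the noncarcinogenic calculation.

    Defaults describe the child farmer scenario: 15 kg body weight, 250
    exposure days per year over 25 years, 100 mg/day soil ingestion,
    3470 cm² exposed skin with 0.12 mg/cm² soil adherence, 20 m³/day
    inhalation; averaging time AT_n = ED × 365 days.
    """

    thq: float = 1.0
    bw_c: float = 15.0
    ef_r: float = 250.0
    ed_c: float = 25.0
    irs_c: float = 100.0
    sa: float = 3470.0
    af: float = 0.12
    ira_c: float = 20.0
    at_n: float | None = None

    def __post_init__(self):
        if self.at_n is None:
            object.__setattr__(self, "at_n", self.ed_c * 365.0)
        for name in ("thq", "bw_c", "ef_r", "ed_c", "irs_c", "sa", "af", "ira_c", "at_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class CarcScenario:
    """Exposure parameters for the carcinogenic calculation.

    Defaults: target risk 1e-6, 70-year averaging time (25 550 days),
    250 exposure days per year, age-adjusted ingestion/dermal/inhalation
    factors 100, 361 and 11.
    """

    tr: float = 1e-6
    at_c: float = 25550.0
    ef_r: float = 250.0
    ifs_adj: float = 100.0
    sfs_adj: float = 361.0
    inhf_adj: float = 11.0

    def __post_init__(self):
        for name in ("tr", "at_c", "ef_r", "ifs_adj", "sfs_adj", "inhf_adj"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class EffectBasis(str, enum.Enum):
    NONCARCINOGENIC = "noncarcinogenic"
    CARCINOGENIC = "carcinogenic"
    COMBINED = "combined"


def ssl_noncarcinogenic(tox: ToxicityProfile, scen: NoncarcScenario | None = None) -> float:
    """Noncarcinogenic soil screening level, mg/kg."""
    scen = scen or NoncarcScenario()
    if tox.rfd_o is None or tox.rfd_i is None:
        raise ValueError("noncarcinogenic SSL requires rfd_o and rfd_i")
    intake = (
        (1.0 / tox.rfd_o) * (scen.irs_c / _MG_PER_KG)
        + (1.0 / tox.rfd_o) * (scen.sa * scen.af * tox.abs_skin / _MG_PER_KG)
        + (1.0 / tox.rfd_i) * (scen.ira_c / tox.vf_or_pef)
    )
    return (scen.thq * scen.bw_c * scen.at_n) / (scen.ef_r * scen.ed_c * intake)


def ssl_carcinogenic(tox: ToxicityProfile, scen: CarcScenario | None = None) -> float:
    """Carcinogenic soil screening level, mg/kg."""
    scen = scen or CarcScenario()
    if tox.csf_o is None or tox.csf_i is None:
        raise ValueError("carcinogenic SSL requires csf_o and csf_i")
    intake = (
        scen.ifs_adj * tox.csf_o / _MG_PER_KG
        + scen.sfs_adj * tox.abs_skin * tox.csf_o / _MG_PER_KG
        + scen.inhf_adj * tox.csf_i / tox.vf_or_pef
    )
    return (scen.tr * scen.at_c) / (scen.ef_r * intake)


def screening_level(
    tox: ToxicityProfile,
    basis: EffectBasis | str = EffectBasis.COMBINED,
    noncarc: NoncarcScenario | None = None,
    carc: CarcScenario | None = None,
) -> float:
    """SSL under a chosen effect basis.

    ``combined`` takes the per-compound minimum of the noncarcinogenic and
    carcinogenic levels (conservative) using whichever toxicity routes are
    available; a compound must support at least one.
    """
    basis = EffectBasis(basis)
    if basis is EffectBasis.NONCARCINOGENIC:
        return ssl_noncarcinogenic(tox, noncarc)
    if basis is EffectBasis.CARCINOGENIC:
        return ssl_carcinogenic(tox, carc)
    candidates = []
    if tox.rfd_o is not None and tox.rfd_i is not None:
        candidates.append(ssl_noncarcinogenic(tox, noncarc))
    if tox.csf_o is not None and tox.csf_i is not None:
        candidates.append(ssl_carcinogenic(tox, carc))
    if not candidates:
        raise ValueError("no toxicity route available for combined basis")
    return min(candidates)


def hazard_quotient(pec_ug_kg, ssl_mg_kg) -> np.ndarray | float:
    """HQ = PEC/SSL with the μg/kg → mg/kg conversion done here, nowhere else."""
    pec = np.asarray(pec_ug_kg, dtype=float)
    ssl = np.asarray(ssl_mg_kg, dtype=float)
    if np.any(ssl <= 0):
        raise ValueError("screening level must be positive")
    if np.any(pec < 0):
        raise ValueError("concentration must be non-negative")
    hq = (pec / 1000.0) / ssl
    return float(hq) if hq.ndim == 0 else hq


def hazard_index(hq) -> tuple[float, bool]:
    """Additive hazard index and whether it exceeds the benchmark of 1."""
    arr = np.asarray(hq, dtype=float)
    if np.any(arr < 0):
        raise ValueError("hazard quotients must be non-negative")
    hi = float(arr.sum())
    return hi, hi > 1.0


def risk_contributions(hq) -> np.ndarray:
    """Closed composition of per-compound shares of the hazard index."""
    arr = np.asarray(hq, dtype=float)
    hi, _ = hazard_index(arr)
    if hi <= 0:
        raise ValueError("contributions undefined at zero hazard index")
    return arr / hi


@dataclass(frozen=True)
class HazardResult:
    """Per-site screening outcome."""

    compound_ids: tuple[str, ...]
    hq: np.ndarray
    hi: float
    exceeds_benchmark: bool
    contributions: np.ndarray | None
    effect_basis: EffectBasis


def evaluate_site(
    pec_ug_kg,
    toxicity: dict[str, ToxicityProfile],
    compound_ids=None,
    basis: EffectBasis | str = EffectBasis.COMBINED,
    noncarc: NoncarcScenario | None = None,
    carc: CarcScenario | None = None,
) -> HazardResult:
    """Screen one site's concentration vector against per-compound SSLs."""
    basis = EffectBasis(basis)
    ids = tuple(compound_ids) if compound_ids is not None else tuple(toxicity)
    pec = np.asarray(pec_ug_kg, dtype=float)
    if pec.shape != (len(ids),):
        raise ValueError("concentration vector length must match compound ids")
    ssl = np.array(
        [screening_level(toxicity[cid], basis, noncarc, carc) for cid in ids]
    )
    hq = hazard_quotient(pec, ssl)
    hi, exceeds = hazard_index(hq)
    contributions = risk_contributions(hq) if hi > 0 else None
    return HazardResult(ids, hq, hi, exceeds, contributions, basis)


def evaluate_table(
    table,
    toxicity: dict[str, ToxicityProfile],
    basis: EffectBasis | str = EffectBasis.COMBINED,
    noncarc: NoncarcScenario | None = None,
    carc: CarcScenario | None = None,
) -> pd.DataFrame:
    """Screen every site of a SampleTable; wide per-site output.

    Columns: ``hq_<id>`` per compound, ``hi``, ``exceeds_benchmark``, and
    the contribution composition ``p_<id>`` (NaN for an all-zero site).
    """
    ids = table.compound_ids
    basis = EffectBasis(basis)
    ssl = np.array([screening_level(toxicity[c], basis, noncarc, carc) for c in ids])
    hq = hazard_quotient(table.concentrations, ssl[None, :])
    hi = hq.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(hi[:, None] > 0, hq / np.where(hi[:, None] > 0, hi[:, None], 1.0), np.nan)
    out = pd.DataFrame(index=pd.Index(list(table.site_ids), name="site_id"))
    for j, cid in enumerate(ids):
        out[f"hq_{cid}"] = hq[:, j]
    out["hi"] = hi
    out["exceeds_benchmark"] = hi > 1.0
    for j, cid in enumerate(ids):
        out[f"p_{cid}"] = p[:, j]
    return out


def load_toxicity(path) -> dict[str, ToxicityProfile]:
    """Read per-compound toxicity criteria from CSV (blank = absent).

    Columns: id, rfd_o, rfd_i, csf_o, csf_i, abs_skin, vf_s, pef,
    volatile_flag.
    """
    frame = pd.read_csv(path, dtype={"id": str})
    if "id" not in frame.columns:
        raise ValueError("toxicity CSV needs an 'id' column")

    def opt(row, col):
        if col not in frame.columns or pd.isna(row[col]):
            return None
        return float(row[col])

    out: dict[str, ToxicityProfile] = {}
    for _, row in frame.iterrows():
        out[row["id"]] = ToxicityProfile(
            rfd_o=opt(row, "rfd_o"),
            rfd_i=opt(row, "rfd_i"),
            csf_o=opt(row, "csf_o"),
            csf_i=opt(row, "csf_i"),
            abs_skin=float(row.get("abs_skin", 0.1)),
            vf_s=opt(row, "vf_s"),
            pef=opt(row, "pef"),
            volatile_flag=bool(row.get("volatile_flag", False)),
        )
    return out


def write_toxicity(toxicity: dict[str, ToxicityProfile], path) -> None:
    pd.DataFrame(
        [
            {
                "id": cid,
                "rfd_o": t.rfd_o,
                "rfd_i": t.rfd_i,
                "csf_o": t.csf_o,
                "csf_i": t.csf_i,
                "abs_skin": t.abs_skin,
                "vf_s": t.vf_s,
                "pef": t.pef,
                "volatile_flag": t.volatile_flag,
            }
            for cid, t in toxicity.items()
        ]
    ).to_csv(path, index=False)


def load_scenarios(path) -> tuple[NoncarcScenario, CarcScenario]:
    """Read exposure scenarios from a YAML/JSON file with two blocks.

    The ``noncarcinogenic`` block takes thq, bw_c, at_n, ef_r, ed_c,
    irs_c, sa, af, ira_c; the ``carcinogenic`` block takes tr, at_c,
    ef_r, ifs_adj, sfs_adj, inhf_adj. Missing keys keep their defaults.
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return (
        NoncarcScenario(**(cfg.get("noncarcinogenic") or {})),
        CarcScenario(**(cfg.get("carcinogenic") or {})),
    )
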