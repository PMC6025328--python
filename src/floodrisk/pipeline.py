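"""End-to-end survey analysis: load → screen → explore → cluster → report.

``run_pipeline`` chains every stage of the workflow on one survey —
half-DL substitution, per-site hazard screening, closure of the
contribution compositions, robust compositional PCA, representative
subcomposition and ternary coordinates, PCoA of Aitchison distances,
fuzzy c-means and cluster profiles — and writes each product as CSV plus
a machine-readable run report. Outputs are a pure function of the inputs
and the seed: rerunning with identical configuration yields byte-identical
files.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, cluster, coda, io, multivariate, risk, synthetic

__all__ = ["RunConfig", "run_pipeline", "compound_family"]

log = logging.getLogger("floodrisk.pipeline")


def compound_family(compound: io.CompoundDescriptor) -> str:
    """Archetype family of a compound: PAH, DDX, or mixed organochlorine."""
    if compound.group is io.Group.PAH:
        return "PAH"
    if "DD" in compound.id:
        return "DDX"
    return "OC"


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    outdir: str | Path
    samples: str | Path | None = None  # None → synthetic survey
    registry: str | Path | None = None
    toxicity: str | Path | None = None
    scenario: str | Path | None = None
    effect_basis: str = "combined"
    robust: bool = True
    n_clusters: int = 3
    cluster_range: tuple[int, ...] = (2, 3, 4, 5)
    fuzzifier: float = 2.0
    seed: int = 0
    n_sites: int = 100

    def echo(self) -> dict:
        return {
            "outdir": str(self.outdir),
            "samples": None if self.samples is None else str(self.samples),
            "registry": None if self.registry is None else str(self.registry),
            "toxicity": None if self.toxicity is None else str(self.toxicity),
            "scenario": None if self.scenario is None else str(self.scenario),
            "effect_basis": self.effect_basis,
            "robust": self.robust,
            "n_clusters": self.n_clusters,
            "cluster_range": list(self.cluster_range),
            "fuzzifier": self.fuzzifier,
            "seed": self.seed,
            "n_sites": self.n_sites,
        }


def _write(frame: pd.DataFrame, path: Path, created: list[Path]) -> None:
    frame.to_csv(path, float_format="%.12g")
    created.append(path)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the run report (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    report: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.echo(),
        "warnings": [],
    }
    stage = "setup"
    t0 = time.perf_counter()
    try:
        stage = "load"
        if config.samples is not None:
            if config.registry is None:
                raise ValueError("a samples file requires a registry file")
            registry = io.load_registry(config.registry)
            table = io.load_samples(config.samples, registry)
        else:
            cfg = synthetic.SurveyConfig(n_sites=config.n_sites, seed=config.seed)
            table, true_labels, true_p = synthetic.generate_survey(cfg)
            truth = table.to_frame().iloc[:, :0].copy()
            truth["true_archetype"] = true_labels
            for j, cid in enumerate(table.compound_ids):
                truth[f"true_p_{cid}"] = true_p[:, j]
            _write(truth, outdir / "truth.csv", created)
        toxicity = (
            risk.load_toxicity(config.toxicity)
            if config.toxicity is not None
            else synthetic.toxicity_registry()
        )
        if config.scenario is not None:
            noncarc, carc = risk.load_scenarios(config.scenario)
        else:
            noncarc, carc = risk.NoncarcScenario(), risk.CarcScenario()
        log.info("loaded %d sites x %d compounds", len(table.site_ids),
                 len(table.compounds))

        stage = "half-dl"
        table = io.substitute_half_dl(table)
        _write(io.summarize_table(table), outdir / "summary.csv", created)

        stage = "risk"
        hazard = risk.evaluate_table(
            table, toxicity, config.effect_basis, noncarc, carc
        )
        _write(hazard, outdir / "hazard.csv", created)
        n_exceed = int(hazard["exceeds_benchmark"].sum())
        report["n_sites"] = len(table.site_ids)
        report["n_compounds"] = len(table.compounds)
        report["n_sites_hi_above_1"] = n_exceed

        stage = "contributions"
        ids = table.compound_ids
        P = hazard[[f"p_{c}" for c in ids]].to_numpy()
        if np.isnan(P).any():
            raise ValueError("a site has zero hazard index; contributions undefined")
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-8)
        contrib = pd.DataFrame(P, index=hazard.index, columns=ids)
        contrib["hi_above_1"] = hazard["exceeds_benchmark"].to_numpy()
        _write(contrib, outdir / "contributions.csv", created)

        stage = "pca"
        pca = multivariate.CompositionalPCA(
            robust=config.robust, random_state=config.seed
        ).fit(P)
        _write(
            pd.DataFrame(
                pca.loadings_clr_, index=pd.Index(ids, name="part"),
                columns=[f"PC{i + 1}" for i in range(pca.loadings_clr_.shape[1])],
            ),
            outdir / "pca_loadings_clr.csv", created,
        )
        scores = pd.DataFrame(
            pca.scores_, index=hazard.index,
            columns=[f"PC{i + 1}" for i in range(pca.scores_.shape[1])],
        )
        scores["hi_above_1"] = hazard["exceeds_benchmark"].to_numpy()
        _write(scores, outdir / "pca_scores.csv", created)
        report["explained_variance_ratio"] = pca.explained_variance_ratio_.tolist()

        stage = "subcomposition"
        families = {c.id: compound_family(c) for c in table.compounds}
        chosen = multivariate.select_representative_subcomposition(
            pca, ids, families
        )
        report["representative_subcomposition"] = chosen
        sub = coda.subcomposition(P, ids, chosen)
        sub_centered, _ = coda.center_data(sub)
        tern = pd.DataFrame(
            coda.ternary_coords(sub_centered), index=hazard.index, columns=["u", "v"]
        )
        for k, lab in enumerate(chosen):
            tern[lab] = sub_centered[:, k]
        tern["hi_above_1"] = hazard["exceeds_benchmark"].to_numpy()
        _write(tern, outdir / "ternary.csv", created)

        stage = "pcoa"
        import warnings as _warnings

        dist = coda.aitchison_distance_matrix(P)
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            pcoa = multivariate.AitchisonPCoA().fit(dist)
            report["warnings"] += [str(w.message) for w in caught]
        coords = pd.DataFrame(
            pcoa.coordinates_[:, :2], index=hazard.index, columns=["PCo1", "PCo2"]
        )
        coords["hi_above_1"] = hazard["exceeds_benchmark"].to_numpy()
        _write(coords, outdir / "pcoa_coordinates.csv", created)

        stage = "clustering"
        Z = coda.ilr(P)
        scored = cluster.choose_cluster_count(
            Z, config.cluster_range, m=config.fuzzifier, seed=config.seed
        )
        _write(scored, outdir / "cluster_selection.csv", created)
        model = cluster.fcm(
            Z, config.n_clusters, m=config.fuzzifier, seed=config.seed
        )
        member = pd.DataFrame(
            model.membership_, index=hazard.index,
            columns=[f"u_{k + 1}" for k in range(config.n_clusters)],
        )
        member["hard_label"] = model.labels_
        member["hi_above_1"] = hazard["exceeds_benchmark"].to_numpy()
        _write(member, outdir / "memberships.csv", created)

        stage = "profiles"
        P_centered, _ = coda.center_data(P)
        profiles = cluster.cluster_profiles(
            P_centered, model.membership_, labels=ids
        )
        _write(profiles.set_index(["cluster", "part"]),
               outdir / "cluster_profiles.csv", created)

        stage = "report"
        report["outputs"] = sorted(p.name for p in created) + ["report.json"]
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        log.info("pipeline finished in %.1f s", time.perf_counter() - t0)
        return report
    except Exception as exc:
        for path in created:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
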