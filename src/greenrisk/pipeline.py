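"""End-to-end study orchestration.

Runs the full small-area analysis: build (or simulate) the region table,
compute expected counts by indirect standardization, screen each stratum
for spatial autocorrelation with a Moran's I permutation test, fit the
BYM Poisson-lognormal model per stratum (2 sexes x 4 age groups by
default, each with its own chain seeded from the master seed), and write
coefficient tables, the spatial-fraction (psi) table, per-region relative
risks and region map files to the output directory.

Failures are isolated per stratum: a degenerate stratum is recorded in
the report and the remaining strata still run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bym import BYMPoissonModel, PosteriorSummary
from .geography import Geography, generate_lattice, read_edge_list, write_edge_list
from .simulate import (SimulationTruth, simulate_counts, simulate_covariates,
                       simulate_populations)
from .spatial import build_weights, morans_i_permutation
from .standardize import AGE_GROUPS, SEXES, expected, validate_stratum_table

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "StudyReport", "run_study", "export_risk_map"]

ALL_STRATA = tuple((s, a) for s in SEXES for a in AGE_GROUPS)


@dataclass
class StudyConfig:
    """Configuration of one study run (synthetic or real-data mode)."""

    mode: str = "synthetic"                    # "synthetic" | "real"
    # synthetic-mode geometry and truth
    n_rows: int = 10
    n_cols: int = 14
    truth_beta: tuple = (0.0, -4.544, 0.0, 0.0, 0.0, 0.0)
    truth_sigma_u: float = 0.1
    truth_sigma_s: float = 0.5
    # real-mode inputs
    stratum_csv: str | None = None
    covariate_csv: str | None = None
    edge_csv: str | None = None
    # analysis settings
    strata: tuple = ALL_STRATA
    model: dict = field(default_factory=lambda: {
        "n_iterations": 15000, "n_burnin": 5000, "thin": 1})
    moran_n_perm: int = 999
    moran_alternative: str = "greater"
    out_dir: str = "study_out"
    master_seed: int = 0

    def __post_init__(self):
        self.strata = tuple((s, a) for s, a in self.strata)
        bad = [st for st in self.strata if st not in ALL_STRATA]
        if bad:
            raise ValueError(f"unknown strata {bad}")
        if self.mode not in ("synthetic", "real"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "real" and not (self.stratum_csv and self.covariate_csv
                                        and self.edge_csv):
            raise ValueError("real mode needs stratum, covariate and edge CSVs")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "strata" in raw:
            raw["strata"] = tuple(tuple(st) for st in raw["strata"])
        if "truth_beta" in raw:
            raw["truth_beta"] = tuple(raw["truth_beta"])
        return cls(**raw)


@dataclass
class StudyReport:
    """Per-stratum results plus a provenance block."""

    strata: dict                  # (sex, age) -> dict of results
    provenance: dict

    def coefficient_table(self) -> pd.DataFrame:
        rows = []
        for (sex, ag), res in self.strata.items():
            if "error" in res:
                continue
            coef = res["summary"].coefficients
            for name, r in coef.iterrows():
                rows.append({"sex": sex, "age_group": ag, "coefficient": name,
                             "mean": r["mean"], "q025": r["q025"],
                             "q975": r["q975"],
                             "significant": bool(r["significant"])})
        return pd.DataFrame(rows)

    def psi_table(self) -> pd.DataFrame:
        rows = []
        for (sex, ag), res in self.strata.items():
            if "error" in res:
                continue
            m, lo, hi = res["summary"].psi
            rows.append({"sex": sex, "age_group": ag, "psi_mean": m,
                         "psi_q025": lo, "psi_q975": hi})
        return pd.DataFrame(rows)

    def moran_table(self) -> pd.DataFrame:
        rows = []
        for (sex, ag), res in self.strata.items():
            if "moran_i" not in res:
                continue
            rows.append({"sex": sex, "age_group": ag,
                         "moran_i_log_sir": res["moran_i"],
                         "moran_p_log_sir": res["moran_p"],
                         "moran_i_counts": res["moran_i_raw"],
                         "moran_p_counts": res["moran_p_raw"]})
        return pd.DataFrame(rows)


def _subgraph_edges(geog: Geography, keep: np.ndarray) -> np.ndarray:
    """Edge array of the subgraph induced by boolean mask ``keep``, reindexed."""
    newidx = np.cumsum(keep) - 1
    e = geog.edges
    mask = keep[e[:, 0]] & keep[e[:, 1]]
    return np.column_stack([newidx[e[mask, 0]], newidx[e[mask, 1]]]).astype(np.intp)


def run_study(config: StudyConfig):
    """Execute the configured study; returns (StudyReport, Geography) and
    writes report artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.master_seed)

    if config.mode == "synthetic":
        geog = generate_lattice(config.n_rows, config.n_cols)
        covariates = simulate_covariates(geog, seed=seed + 1)
        populations = simulate_populations(geog, seed=seed + 2)
        truth = SimulationTruth(beta=tuple(config.truth_beta),
                                sigma_u=config.truth_sigma_u,
                                sigma_s=config.truth_sigma_s, seed=seed + 3)
        counts = simulate_counts(geog, covariates, populations, truth)
        counts = counts.drop(columns=["expected"])
        write_edge_list(geog, out / "adjacency.csv")
        covariates.to_csv(out / "covariates.csv", index=False)
        counts.to_csv(out / "stratum_table.csv", index=False)
    else:
        counts = pd.read_csv(config.stratum_csv)
        covariates = pd.read_csv(config.covariate_csv)
        geog = read_edge_list(config.edge_csv,
                              region_ids=list(dict.fromkeys(
                                  pd.read_csv(config.stratum_csv)["region_id"]
                                  .astype(str))))
        counts["region_id"] = counts["region_id"].astype(str)
        covariates["region_id"] = covariates["region_id"].astype(str)

    counts = validate_stratum_table(counts)
    with_expected = expected(counts)

    ids = list(geog.region_ids)
    cov = covariates.set_index("region_id")
    if set(cov.index) != set(ids):
        raise ValueError("covariate regions do not match the geography")
    X_full = cov.loc[ids, ["X1", "X2", "X3", "X4", "X5"]].to_numpy(dtype=float)
    W = build_weights(geog, style="row")

    results = {}
    for offset, (sex, ag) in enumerate(ALL_STRATA):
        if (sex, ag) not in config.strata:
            continue
        res = {}
        try:
            sub = with_expected[(with_expected["sex"] == sex)
                                & (with_expected["age_group"] == ag)]
            sub = sub.set_index("region_id").loc[ids]
            y = sub["observed"].to_numpy(dtype=float)
            E = sub["expected"].to_numpy(dtype=float)
            keep = E > 0
            excluded = [ids[i] for i in np.flatnonzero(~keep)]
            if excluded:
                logger.warning("stratum (%s, %s): excluding %d region(s) "
                               "with E=0", sex, ag, len(excluded))
            res["excluded"] = excluded

            stratum_seed = seed + 100 + offset
            log_sir = np.log((y[keep] + 0.5) / E[keep])
            if keep.all():
                Wk = W
            else:
                Wk = build_weights(
                    Geography(tuple(np.asarray(ids)[keep]),
                              _edges_to_neighbors(
                                  _subgraph_edges(geog, keep),
                                  int(keep.sum()))),
                    style="row")
            i_t, p_t = morans_i_permutation(
                log_sir, Wk, n_perm=config.moran_n_perm, seed=stratum_seed,
                alternative=config.moran_alternative)
            i_r, p_r = morans_i_permutation(
                y[keep], Wk, n_perm=config.moran_n_perm, seed=stratum_seed,
                alternative=config.moran_alternative)
            res.update(moran_i=i_t, moran_p=p_t, moran_i_raw=i_r,
                       moran_p_raw=p_r)

            model = BYMPoissonModel(random_state=stratum_seed, **config.model)
            adj = (geog if keep.all()
                   else _subgraph_edges(geog, keep))
            model.fit(X_full[keep], y[keep], expected=E[keep], adjacency=adj)
            res["summary"] = model.summary_
            res["model"] = model

            rr = model.summary_.relative_risk.copy()
            rr.insert(0, "region_id", np.asarray(ids)[keep])
            rr["exceedance"] = rr["rr_mean"] > 1
            rr.to_csv(out / f"rr_{sex}_{ag.replace('>=', 'ge')}.csv",
                      index=False)
        except Exception as exc:  # stratum isolation: record and continue
            logger.exception("stratum (%s, %s) failed", sex, ag)
            res["error"] = f"{type(exc).__name__}: {exc}"
        results[(sex, ag)] = res

    report = StudyReport(
        strata=results,
        provenance={
            "package_version": __version__,
            "master_seed": seed,
            "mode": config.mode,
            "model": dict(config.model),
            "n_regions": geog.n_regions,
            "strata_run": [list(st) for st in config.strata],
        },
    )
    report.coefficient_table().to_csv(out / "coefficients.csv", index=False)
    report.psi_table().to_csv(out / "psi.csv", index=False)
    report.moran_table().to_csv(out / "moran.csv", index=False)
    with open(out / "provenance.json", "w") as fh:
        json.dump(report.provenance, fh, indent=2, sort_keys=True)
    return report, geog


def _edges_to_neighbors(edges: np.ndarray, n: int) -> tuple:
    nbrs = [set() for _ in range(n)]
    for i, j in edges:
        nbrs[int(i)].add(int(j))
        nbrs[int(j)].add(int(i))
    return tuple(tuple(sorted(s)) for s in nbrs)


def export_risk_map(summary: PosteriorSummary, geog: Geography, path) -> Path:
    """Write per-region relative-risk records as GeoJSON (lattice polygons)
    or CSV when no coordinates exist.

    Each record carries the posterior mean r_i, the 95% bounds, and an
    exceedance flag marking r_i > 1 (elevated area-specific risk).
    """
    rr = summary.relative_risk
    if len(rr) != geog.n_regions:
        raise ValueError("summary regions do not align with the geography")
    path = Path(path)
    records = pd.DataFrame({
        "region_id": list(geog.region_ids),
        "rr_mean": rr["rr_mean"].to_numpy(),
        "rr_q025": rr["rr_q025"].to_numpy(),
        "rr_q975": rr["rr_q975"].to_numpy(),
        "exceedance": (rr["rr_mean"] > 1).to_numpy(),
    })
    if geog.coords is None or path.suffix.lower() == ".csv":
        records.to_csv(path.with_suffix(".csv"), index=False)
        return path.with_suffix(".csv")

    from shapely.geometry import box, mapping

    features = []
    for i, row in records.iterrows():
        r, c = (float(v) for v in geog.coords[i])
        geom = box(c, -r - 1, c + 1, -r)  # unit cells, rows increasing downward
        features.append({
            "type": "Feature",
            "geometry": mapping(geom),
            "properties": {
                "region_id": row["region_id"],
                "rr_mean": float(row["rr_mean"]),
                "rr_q025": float(row["rr_q025"]),
                "rr_q975": float(row["rr_q975"]),
                "exceedance": bool(row["exceedance"]),
            },
        })
    gj = {"type": "FeatureCollection", "features": features}
    with open(path, "w") as fh:
        json.dump(gj, fh)
    return path
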