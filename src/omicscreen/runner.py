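"""Scenario-grid orchestration, seeding, and the real-data application path.

A method roster is a list of method names:

* ``"anova_raw05"`` — per-feature F-test, unadjusted p < 0.05;
* ``"anova_fdr05"`` / ``"anova_fdr20"`` — BH-adjusted p < 0.05 / 0.20;
* ``"enet:<alpha>"`` — elastic-net logistic selection at that penalty
  split, lambda chosen by 10-fold CV (e.g. ``"enet:0.5"``, ``"enet:1.0"``).

Seeds form a stable hierarchy (base seed -> scenario -> replicate -> CV
folds) via :class:`numpy.random.SeedSequence`, so any single replicate can
be reproduced in isolation and replicate results do not depend on
execution order.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .anova import anova_screen, bh_adjust, anova_f_test, select_features
from .enet import EnetConfig, cv_select_lambda, labels_to_binary
from .metrics import MetricsRecord, aggregate_metrics, classify_outcomes, records_to_frame
from .simulate import ScenarioSpec, simulate_dataset

__all__ = [
    "GridSpec",
    "parse_method",
    "run_methods_on_dataset",
    "run_scenario",
    "run_grid",
    "apply_to_table",
]

logger = logging.getLogger(__name__)

ANOVA_METHODS = ("anova_raw05", "anova_fdr05", "anova_fdr20")
DEFAULT_ALPHAS = tuple(round(0.1 * i, 1) for i in range(11))


def parse_method(name: str) -> tuple[str, float | None]:
    """Split a method name into (kind, alpha)."""
    if name in ANOVA_METHODS:
        return name, None
    if name.startswith("enet:"):
        alpha = float(name.split(":", 1)[1])
        if not 0.0 <= alpha <= 1.0:
            raise ValueError(f"enet alpha out of range in {name!r}")
        return "enet", alpha
    raise ValueError(f"unknown method {name!r}")


def _scenario_key(spec: ScenarioSpec) -> int:
    """Stable 31-bit integer identifying a scenario for seed derivation."""
    return zlib.crc32(spec.scenario_id.encode()) & 0x7FFFFFFF


def _replicate_seeds(spec: ScenarioSpec, base_seed: int, r: int):
    """(data seed sequence, CV fold seed) for replicate ``r``."""
    ss = np.random.SeedSequence([int(base_seed), _scenario_key(spec), r])
    data_ss, cv_ss = ss.spawn(2)
    cv_seed = int(cv_ss.generate_state(1)[0] & 0x7FFFFFFF)
    return data_ss, cv_seed


def run_methods_on_dataset(
    values: np.ndarray,
    labels: np.ndarray,
    methods: list[str],
    enet_config: EnetConfig | None = None,
    cv_seed: int = 0,
) -> dict[str, np.ndarray]:
    """Run every method on one dataset; returns method -> boolean selection."""
    selections: dict[str, np.ndarray] = {}
    anova_wanted = [m for m in methods if m in ANOVA_METHODS]
    if anova_wanted:
        res = anova_screen(values, labels)
        cols = {
            "anova_raw05": res.selected_raw05,
            "anova_fdr05": res.selected_fdr05,
            "anova_fdr20": res.selected_fdr20,
        }
        for m in anova_wanted:
            selections[m] = cols[m]
    y01 = labels_to_binary(labels)
    base = enet_config or EnetConfig()
    for m in methods:
        kind, alpha = parse_method(m)
        if kind != "enet":
            continue
        from dataclasses import replace

        cfg = replace(base, alpha=alpha, seed=cv_seed)
        fit = cv_select_lambda(values, y01, cfg)
        selections[m] = fit.selected
    return selections


def run_scenario(
    spec: ScenarioSpec,
    methods: list[str],
    replicates: int,
    base_seed: int,
    enet_config: EnetConfig | None = None,
) -> list[MetricsRecord]:
    """Simulate ``replicates`` datasets and aggregate each method's metrics.

    A method failure on one replicate is logged with its child seed and
    that replicate is excluded from the failing method's aggregation only.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    for m in methods:
        parse_method(m)
    outcomes: dict[str, list[dict[str, float]]] = {m: [] for m in methods}
    failures: dict[str, int] = {m: 0 for m in methods}
    for r in range(replicates):
        data_ss, cv_seed = _replicate_seeds(spec, base_seed, r)
        rng = np.random.default_rng(data_ss)
        ds = simulate_dataset(spec, rng)
        for m in methods:
            try:
                sel = run_methods_on_dataset(
                    ds.values, ds.labels, [m], enet_config, cv_seed
                )[m]
            except Exception:
                failures[m] += 1
                logger.warning(
                    "method %s failed on replicate %d of %s (cv_seed=%d); "
                    "replicate excluded",
                    m, r, spec.scenario_id, cv_seed, exc_info=True,
                )
                continue
            outcomes[m].append(classify_outcomes(sel, ds.truth))
    records: list[MetricsRecord] = []
    for m in methods:
        if failures[m]:
            logger.warning(
                "%s: %d/%d replicates excluded for %s",
                spec.scenario_id, failures[m], replicates, m,
            )
        if not outcomes[m]:
            continue
        _, alpha = parse_method(m)
        records.extend(
            aggregate_metrics(outcomes[m], spec.scenario_id, m, alpha)
        )
    return records


@dataclass(frozen=True)
class GridSpec:
    """The full scenario grid: feature layouts x correlations x sample sizes.

    The default grid is 2 layouts x 2 correlations x 5 sample sizes = 20
    scenarios; the extension adds n in {200, 500, 1000} at the larger
    layout with rho = 0.4.
    """

    layouts: tuple[tuple[int, int], ...] = ((35, 100), (350, 1000))
    rho_values: tuple[float, ...] = (0.4, 0.8)
    n_values: tuple[int, ...] = (10, 20, 30, 50, 100)
    extension_n: tuple[int, ...] = ()  # e.g. (200, 500, 1000)
    deltas: tuple[float, ...] = (0.2, 0.5, 0.8)
    alphas: tuple[float, ...] = DEFAULT_ALPHAS
    anova_methods: tuple[str, ...] = ANOVA_METHODS
    replicates: int = 200
    base_seed: int = 0

    @property
    def methods(self) -> list[str]:
        return list(self.anova_methods) + [f"enet:{a:g}" for a in self.alphas]

    def scenarios(self) -> list[ScenarioSpec]:
        out = []
        for block_size, noise_count in self.layouts:
            for rho in self.rho_values:
                for n in self.n_values:
                    out.append(
                        ScenarioSpec(
                            block_size=block_size,
                            noise_count=noise_count,
                            rho=rho,
                            n_total=n,
                            deltas=self.deltas,
                        )
                    )
        big = max(self.layouts, key=lambda x: x[0])
        for n in self.extension_n:
            out.append(
                ScenarioSpec(
                    block_size=big[0], noise_count=big[1], rho=0.4,
                    n_total=n, deltas=self.deltas,
                )
            )
        return out

    def to_dict(self) -> dict:
        return {
            "layouts": [list(x) for x in self.layouts],
            "rho_values": list(self.rho_values),
            "n_values": list(self.n_values),
            "extension_n": list(self.extension_n),
            "deltas": list(self.deltas),
            "alphas": list(self.alphas),
            "anova_methods": list(self.anova_methods),
            "replicates": self.replicates,
            "base_seed": self.base_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        d = dict(d)
        for key in ("layouts",):
            if key in d:
                d[key] = tuple(tuple(x) for x in d[key])
        for key in ("rho_values", "n_values", "extension_n", "deltas",
                    "alphas", "anova_methods"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GridSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def run_grid(
    grid: GridSpec,
    out_dir: str | Path,
    enet_config: EnetConfig | None = None,
    resume: bool = False,
) -> pd.DataFrame:
    """Run every scenario in the grid; tidy CSV plus manifest in ``out_dir``.

    Per-scenario CSVs are written as they complete, so an interrupted run
    can be resumed (``resume=True`` skips scenarios whose output exists;
    without it a partial output directory is an error).
    """
    out_dir = Path(out_dir)
    scen_dir = out_dir / "scenarios"
    scen_dir.mkdir(parents=True, exist_ok=True)
    config_str = json.dumps(grid.to_dict(), sort_keys=True)
    config_hash = f"{zlib.crc32(config_str.encode()):08x}"
    manifest_path = out_dir / "manifest.json"
    existing = sorted(x.name for x in scen_dir.glob("*.csv"))
    if existing and not resume:
        raise FileExistsError(
            f"{scen_dir} already holds {len(existing)} scenario outputs; "
            f"pass resume=True to continue or choose a fresh directory"
        )
    frames = []
    for spec in grid.scenarios():
        path = scen_dir / f"{spec.scenario_id}.csv"
        if resume and path.exists():
            logger.info("skipping completed scenario %s", spec.scenario_id)
            frames.append(pd.read_csv(path))
            continue
        logger.info("running scenario %s", spec.scenario_id)
        records = run_scenario(
            spec, grid.methods, grid.replicates, grid.base_seed, enet_config
        )
        df = records_to_frame(records)
        df.insert(1, "p", spec.p)
        df.insert(2, "rho", spec.rho)
        df.insert(3, "n", spec.n_total)
        df.to_csv(path, index=False)
        frames.append(df)
    combined = pd.concat(frames, ignore_index=True)
    combined.to_csv(out_dir / "metrics.csv", index=False)
    manifest = {
        "config": grid.to_dict(),
        "config_hash": config_hash,
        "base_seed": grid.base_seed,
        "n_scenarios": len(frames),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return combined


def _read_labels(labels_path: str | Path) -> pd.Series:
    lab = pd.read_csv(labels_path, sep=None, engine="python", header=None,
                      comment="#", dtype=str)
    if lab.shape[1] < 2:
        raise ValueError("labels file needs two columns: sample_id, group")
    # tolerate a header row
    first = lab.iloc[0]
    if first.iloc[0].lower() in ("sample", "sample_id", "id"):
        lab = lab.iloc[1:]
    return pd.Series(lab.iloc[:, 1].values, index=lab.iloc[:, 0].values)


def apply_to_table(
    table_path: str | Path,
    labels_path: str | Path,
    methods: list[str],
    strata_path: str | Path | None = None,
    enet_config: EnetConfig | None = None,
    cv_seed: int = 0,
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Run the selection methods on a real feature table.

    ``table_path`` is a wide CSV/TSV with features in rows (first column =
    feature id) and samples in columns; ``labels_path`` maps each sample to
    one of two groups.  If ``strata_path`` maps features to strata (e.g.
    ionization modes), the BH adjustment is applied separately within each
    stratum.  Returns per-method selected feature-id lists and a pairwise
    overlap-count table.
    """
    table = pd.read_csv(table_path, sep=None, engine="python", index_col=0)
    if table.index.duplicated().any():
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids in table: {dups[:5]}")
    values = table.T  # samples x features
    try:
        X = values.to_numpy(dtype=float)
    except (TypeError, ValueError) as err:
        raise ValueError(f"non-numeric cells in feature table: {err}") from err

    labels = _read_labels(labels_path)
    missing = [s for s in values.index if s not in labels.index]
    if missing:
        raise ValueError(f"samples missing from labels file: {missing}")
    y = labels.loc[values.index]
    groups = sorted(y.unique())
    if len(groups) != 2:
        raise ValueError(f"expected two groups in labels, got {groups}")
    ynum = np.where(y.values == groups[0], 1, 2)

    feature_ids = list(table.index)
    strata = None
    if strata_path is not None:
        smap = pd.read_csv(strata_path, sep=None, engine="python", header=None,
                           dtype=str)
        strata = pd.Series(smap.iloc[:, 1].values, index=smap.iloc[:, 0].values)
        unknown = [f for f in feature_ids if f not in strata.index]
        if unknown:
            raise ValueError(f"features missing from strata file: {unknown[:5]}")

    selections: dict[str, np.ndarray] = {}
    anova_wanted = [m for m in methods if m in ANOVA_METHODS]
    if anova_wanted:
        _, p_raw = anova_f_test(X, ynum)
        if strata is None:
            p_adj = bh_adjust(p_raw)
        else:
            p_adj = np.empty_like(p_raw)
            svals = strata.loc[feature_ids].values
            for s in np.unique(svals):
                mask = svals == s
                p_adj[mask] = bh_adjust(p_raw[mask])
        table_sel = {
            "anova_raw05": select_features(p_raw, p_adj, "raw", 0.05),
            "anova_fdr05": select_features(p_raw, p_adj, "fdr", 0.05),
            "anova_fdr20": select_features(p_raw, p_adj, "fdr", 0.20),
        }
        for m in anova_wanted:
            selections[m] = table_sel[m]
    enet_methods = [m for m in methods if m not in ANOVA_METHODS]
    if enet_methods:
        selections.update(
            run_methods_on_dataset(X, ynum, enet_methods, enet_config, cv_seed)
        )

    lists = {
        m: [feature_ids[i] for i in np.nonzero(sel)[0]]
        for m, sel in selections.items()
    }
    names = list(selections)
    overlap = pd.DataFrame(
        [
            [int((selections[a] & selections[b]).sum()) for b in names]
            for a in names
        ],
        index=names,
        columns=names,
    )
    return lists, overlap
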