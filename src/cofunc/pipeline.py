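"""End-to-end analysis: load inputs, run all concentration tests, report.

The full battery mirrors the three facets of concentration:

* inter-chromosomal dispersal -- mean chromosome count per group (global
  permutations, small is concentrated) and the dispersal tail test on the
  chromosome-count histogram (natural integer bins);
* intra-chromosomal distance -- mean over groups of the mean linear
  distance d_i between same-chromosome member pairs (within-chromosome
  permutations) and the 20-bin tail test on the d_i values;
* spatial (3D) arrangement -- group-mean 1-correlation distance over all
  pairs (global permutations), over inter-chromosomal pairs only
  (within-chromosome permutations, which hold each group's inter-pair count
  fixed), and the tail test on individual inter-chromosomal pair distances.

One batch of permutation replicates per (collection, scheme) feeds every
test and the per-group empirical p-values, so a report is reproducible from
config + seed alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .engine import PermutationEngine
from .genome import (
    GenomeLayout,
    load_family_table,
    load_gene_positions,
    merge_tandem_duplicates,
)
from .groups import GroupCollection, load_groups, restrict_to_layout, summarize
from .permutation import empirical_p
from .spatial import ContactMap, load_contact_map
from .stats import STATISTICS, StatisticUndefinedError
from .tailtest import (
    TailTestResult,
    _tail_from_prefixes,
    bin_count_prefixes,
    integer_thresholds,
    quantile_thresholds,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GroupFileSpec",
    "AnalysisConfig",
    "AnalysisReport",
    "run_analysis",
    "per_group_report",
    "SCALAR_TESTS",
    "TAIL_TESTS",
    "ALL_TESTS",
]

#: scalar permutation tests: name -> registered statistic
SCALAR_TESTS = (
    "mean_chrom_count",
    "intra_linear_group_mean",
    "spatial_all_group_mean",
    "spatial_inter_group_mean",
    "spatial_inter_pairs",
)

#: tail tests: name -> (engine quantity, scheme)
TAIL_TESTS: dict[str, tuple[str, str]] = {
    "chrom_tail": ("chrom_counts", "global"),
    "intra_linear_tail": ("linear_group_means", "within_chromosome"),
    "spatial_inter_pairs_tail": ("spatial_inter_pair_dists", "within_chromosome"),
}

ALL_TESTS = SCALAR_TESTS + tuple(TAIL_TESTS)

_NEEDS_MAP = {
    "spatial_all_group_mean",
    "spatial_inter_group_mean",
    "spatial_inter_pairs",
    "spatial_inter_pairs_tail",
}


@dataclass(frozen=True)
class GroupFileSpec:
    path: str
    format: str  # pairs | gmt
    group_type: str  # ppi | complex | pathway


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything needed to reproduce one analysis run."""

    genome_path: str
    group_files: tuple[GroupFileSpec, ...]
    genome_format: str = "bed"
    families_path: str | None = None
    contact_map_path: str | None = None
    contact_map_format: str = "dense_tsv"
    segment_size: int | None = None
    min_overlap: int = 10
    tests: tuple[str, ...] | None = None  # None = all feasible
    n_permutations: int = 999
    k_bins: int = 20
    alpha: float = 0.05
    seed: int = 0
    merge_tandem: bool = True
    per_group_p: bool = True

    def __post_init__(self) -> None:
        for t in self.tests or ():
            if t not in ALL_TESTS:
                raise ValueError(f"unknown test {t!r}")
        if self.tests and self.contact_map_path is None:
            spatial = [t for t in self.tests if t in _NEEDS_MAP]
            if spatial:
                raise ValueError(
                    f"tests {spatial} require a contact map but none is configured"
                )

    def selected_tests(self) -> tuple[str, ...]:
        if self.tests is not None:
            return self.tests
        if self.contact_map_path is None:
            return tuple(t for t in ALL_TESTS if t not in _NEEDS_MAP)
        return ALL_TESTS

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["group_files"] = [dataclasses.asdict(g) for g in self.group_files]
        d["tests"] = list(self.tests) if self.tests is not None else None
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "AnalysisConfig":
        d = dict(d)
        d["group_files"] = tuple(
            GroupFileSpec(**g) if isinstance(g, Mapping) else g
            for g in d.get("group_files", ())
        )
        if d.get("tests") is not None:
            d["tests"] = tuple(d["tests"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        with open(path) as fh:
            d = yaml.safe_load(fh)
        cfg = cls.from_dict(d)
        # resolve input paths relative to the config file
        base = path.parent

        def resolve(p: str | None) -> str | None:
            return None if p is None else str((base / p) if not Path(p).is_absolute() else Path(p))

        return dataclasses.replace(
            cfg,
            genome_path=resolve(cfg.genome_path),  # type: ignore[arg-type]
            families_path=resolve(cfg.families_path),
            contact_map_path=resolve(cfg.contact_map_path),
            group_files=tuple(
                dataclasses.replace(g, path=resolve(g.path))  # type: ignore[arg-type]
                for g in cfg.group_files
            ),
        )


@dataclass
class AnalysisReport:
    """Machine-readable results of one run."""

    summary: dict[str, Any]
    per_group: dict[str, pd.DataFrame]
    tails: dict[tuple[str, str], TailTestResult]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "summary.json", "w") as fh:
            json.dump(_jsonify(self.summary), fh, indent=2, sort_keys=True)
            fh.write("\n")
        for gtype, table in self.per_group.items():
            table.to_csv(
                out / f"per_group_{gtype}.tsv",
                sep="\t",
                index=False,
                na_rep="NA",
                float_format="%.10g",
            )
        for (gtype, test), res in self.tails.items():
            t = np.asarray(res.thresholds.thresholds)
            df = pd.DataFrame(
                {
                    "bin": np.arange(1, res.thresholds.k + 1),
                    "t_lo": t[:-1],
                    "t_hi": t[1:],
                    "F_real": res.prefixes_real,
                    "F_replicate_mean": res.prefixes_replicates.mean(axis=0),
                    "F_replicate_sd": res.prefixes_replicates.std(axis=0),
                    "p_j": res.p_values,
                }
            )
            df.to_csv(
                out / f"tail_{gtype}_{test}.tsv",
                sep="\t",
                index=False,
                float_format="%.10g",
            )


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        f = float(obj)
        return None if np.isnan(f) else f
    return obj


def _load_inputs(
    config: AnalysisConfig,
) -> tuple[GenomeLayout, list[GroupCollection], ContactMap | None]:
    layout = load_gene_positions(config.genome_path, config.genome_format)
    if config.families_path and config.merge_tandem:
        families = load_family_table(config.families_path)
        layout = merge_tandem_duplicates(layout, families)
    collections = []
    for gf in config.group_files:
        coll = load_groups(gf.path, gf.format, gf.group_type)
        collections.append(restrict_to_layout(coll, layout))
    cmap = None
    if config.contact_map_path:
        cmap = load_contact_map(
            config.contact_map_path,
            config.contact_map_format,
            config.segment_size,
            config.min_overlap,
        )
    return layout, collections, cmap


def run_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Execute the configured test battery on every group collection."""
    stage = "load"
    try:
        layout, collections, cmap = _load_inputs(config)
        tests = config.selected_tests()
        seed_rng = np.random.default_rng(config.seed)
        n = config.n_permutations
        summary: dict[str, Any] = {
            "seed": config.seed,
            "n_permutations": n,
            "alpha": config.alpha,
            "k_bins": config.k_bins,
            "tests": list(tests),
            "collections": {},
        }
        per_group_tables: dict[str, pd.DataFrame] = {}
        tails: dict[tuple[str, str], TailTestResult] = {}
        for coll in collections:
            gtype = coll.group_type
            stage = f"analysis[{gtype}]"
            needs_map = cmap is not None and any(t in _NEEDS_MAP for t in tests)
            eng = PermutationEngine(layout, coll, cmap if needs_map else None)
            coll_tests: dict[str, Any] = {}
            # which quantities each scheme must produce
            scheme_quantities: dict[str, set[str]] = {}
            for t in tests:
                if t in TAIL_TESTS:
                    q, scheme = TAIL_TESTS[t]
                else:
                    spec = STATISTICS[t]
                    q, scheme = spec.quantity, spec.scheme
                scheme_quantities.setdefault(scheme, set()).add(q)
            per_group_cols: dict[str, np.ndarray] = {}
            for scheme in ("global", "within_chromosome"):
                if scheme not in scheme_quantities:
                    continue
                quantities = sorted(scheme_quantities[scheme])
                scheme_seed = int(seed_rng.integers(2**31))
                obs = eng.observed(quantities)
                # thresholds for tail tests come from the real values
                tail_specs = {}
                for t in tests:
                    if t in TAIL_TESTS and TAIL_TESTS[t][1] == scheme:
                        q = TAIL_TESTS[t][0]
                        real = obs[q].astype(float)
                        real = real[~np.isnan(real)]
                        if real.size == 0:
                            raise StatisticUndefinedError(
                                f"tail test {t}: no defined real values"
                            )
                        if q == "chrom_counts":
                            thr = integer_thresholds(eng.n_chrom)
                        else:
                            thr = quantile_thresholds(real, config.k_bins)
                        tail_specs[t] = (q, thr, bin_count_prefixes(real, thr))
                scalar_names = [
                    t
                    for t in tests
                    if t in STATISTICS and STATISTICS[t].scheme == scheme
                ]
                scalar_reps = {t: np.empty(n) for t in scalar_names}
                tail_reps = {
                    t: np.empty((n, thr.k), dtype=int)
                    for t, (_, thr, _) in tail_specs.items()
                }
                group_mats = {
                    q: np.empty((n, eng.n_groups))
                    for q in quantities
                    if q != "spatial_inter_pair_dists"
                }
                for r, qvals in enumerate(
                    eng.sample(scheme, n, scheme_seed, quantities)
                ):
                    for t in scalar_names:
                        spec = STATISTICS[t]
                        scalar_reps[t][r] = spec.reduce(qvals[spec.quantity])
                    for t, (q, thr, _) in tail_specs.items():
                        v = qvals[q].astype(float)
                        tail_reps[t][r] = bin_count_prefixes(v[~np.isnan(v)], thr)
                    for q, mat in group_mats.items():
                        mat[r] = qvals[q]
                for t in scalar_names:
                    spec = STATISTICS[t]
                    v0 = spec.reduce(obs[spec.quantity])
                    if np.isnan(v0):
                        raise StatisticUndefinedError(
                            f"statistic {t!r} undefined on the real layout"
                        )
                    res = empirical_p(
                        v0, scalar_reps[t], spec.direction,
                        statistic=t, scheme=scheme, seed=scheme_seed,
                    )
                    coll_tests[t] = {
                        "kind": "scalar",
                        "v0": res.v0,
                        "p_value": res.p_value,
                        "k": res.k,
                        "n": res.n,
                        "direction": res.direction,
                        "scheme": scheme,
                        "seed": scheme_seed,
                    }
                for t, (q, thr, F_real) in tail_specs.items():
                    res = _tail_from_prefixes(
                        thr, F_real, tail_reps[t], config.alpha, seed=scheme_seed
                    )
                    tails[(gtype, t)] = res
                    coll_tests[t] = {
                        "kind": "tail",
                        "j_star": res.j_star,
                        "p_corrected": res.p_corrected,
                        "p_values": res.p_values,
                        "F_real": res.prefixes_real,
                        "n": res.n,
                        "scheme": scheme,
                        "seed": scheme_seed,
                        "k": thr.k,
                    }
                # per-group empirical p from the shared replicate batches
                if config.per_group_p:
                    for q, mat in group_mats.items():
                        wanted_scheme = {
                            "chrom_counts": "global",
                            "linear_group_means": "within_chromosome",
                            "spatial_inter_group_means": "within_chromosome",
                            "spatial_all_group_means": "global",
                        }.get(q)
                        if wanted_scheme != scheme:
                            continue
                        obs_v = obs[q].astype(float)
                        with np.errstate(invalid="ignore"):
                            k_le = np.sum(mat <= obs_v[None, :], axis=0)
                        p_g = np.where(
                            np.isnan(obs_v), np.nan, (k_le + 1) / (n + 1)
                        )
                        per_group_cols[f"p_{q}"] = p_g
            stage = f"report[{gtype}]"
            table = _per_group_table(eng, obs_available=cmap is not None and needs_map)
            for col, vals in per_group_cols.items():
                table[col] = vals
            per_group_tables[gtype] = table
            summary["collections"][gtype] = {
                "n_groups": len(coll),
                "summary": dataclasses.asdict(summarize(coll)) if len(coll) else None,
                "tests": coll_tests,
            }
        return AnalysisReport(summary, per_group_tables, tails)
    except Exception as exc:
        raise RuntimeError(f"analysis failed at stage {stage!r}: {exc}") from exc


def _per_group_table(eng: PermutationEngine, obs_available: bool) -> pd.DataFrame:
    quantities = ["chrom_counts", "linear_group_means"]
    if obs_available:
        quantities += ["spatial_all_group_means", "spatial_inter_group_means"]
    obs = eng.observed(quantities)
    sizes = np.bincount(eng.member_group, minlength=eng.n_groups)
    data: dict[str, Any] = {
        "group_id": eng.group_ids,
        "n_members": sizes,
        "chromosomes_involved": obs["chrom_counts"],
        "d_linear_intra": obs["linear_group_means"],
    }
    if obs_available:
        data["d_spatial_all"] = obs["spatial_all_group_means"]
        data["d_spatial_inter"] = obs["spatial_inter_group_means"]
    return pd.DataFrame(data)


def per_group_report(
    layout: GenomeLayout,
    collections: Sequence[GroupCollection],
    cmap: ContactMap | None = None,
) -> pd.DataFrame:
    """One row per group across all collections with its three per-group
    quantities (chromosome count, linear d_i, spatial d_i); undefined
    entries are NaN, never zero."""
    frames = []
    for coll in collections:
        eng = PermutationEngine(layout, coll, cmap)
        table = _per_group_table(eng, obs_available=cmap is not None)
        table.insert(0, "group_type", coll.group_type)
        frames.append(table)
    return pd.concat(frames, ignore_index=True)


def render_plots(report_dir: str | Path, out_dir: str | Path | None = None) -> list[Path]:
    """Plot real vs mean-replicate cumulative tail curves (+-1 SD bands)
    from a written report directory.  Returns the created figure paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    report_dir = Path(report_dir)
    out = Path(out_dir) if out_dir else report_dir
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for tsv in sorted(report_dir.glob("tail_*.tsv")):
        df = pd.read_csv(tsv, sep="\t")
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(df["bin"], df["F_real"], color="crimson", label="real genome")
        ax.plot(df["bin"], df["F_replicate_mean"], color="steelblue", label="random mean")
        ax.fill_between(
            df["bin"],
            df["F_replicate_mean"] - df["F_replicate_sd"],
            df["F_replicate_mean"] + df["F_replicate_sd"],
            color="steelblue",
            alpha=0.25,
            label="+-1 sd",
        )
        ax.set_xlabel("bin prefix j")
        ax.set_ylabel("cumulative frequency F_j")
        ax.set_title(tsv.stem)
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        png = out / f"{tsv.stem}.png"
        fig.savefig(png, dpi=120)
        plt.close(fig)
        paths.append(png)
    return paths
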