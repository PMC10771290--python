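"""End-to-end study pipeline: grouping, path modeling, cohort selection,
connectivity, similarity and hub analysis.

The flow mirrors the study design: subjects are split into SCD and
non-SCD groups by their memory-complaint sum score (cutoff 20 on the
12-item CCI-S memory scale), a PLS path model is fitted per group with a
permutation multigroup comparison of the personality path, a pooled-model
composite score selects the middle of each group's distribution for the
network stage, per-subject band-limited networks are compared to the
averaged non-SCD network with the spatial similarity index, and
betweenness-centrality hubs are partitioned into shared / lost / gained
sets per band.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .atlas import ROIAtlas, load_default_atlas
from .connectivity import (
    DELTA,
    THETA,
    BandDefinition,
    ConnectivityMatrix,
    build_subject_adjacency,
    group_average_adjacency,
)
from .graph_hubs import detect_hubs, hub_table, plot_venn, venn_partition, weighted_betweenness
from .plssem import (
    ModelSpec,
    compute_composite_scores,
    fit_pls_path_model,
    permutation_multigroup_test,
)
from .siminet import graph_from_adjacency, similarity_index
from .synthetic_data import (
    NetworkSpec,
    generate_coupled_sources,
    generate_hub_network,
    generate_questionnaire_cohort,
    study_cohort_spec,
)

logger = logging.getLogger("scdnet.pipeline")

__all__ = [
    "PipelineConfig",
    "GroupComparison",
    "assign_scd_group",
    "select_middle_cohort",
    "compare_groups",
    "run_full_pipeline",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the full synthetic study run."""

    seed: int = 0
    cci_cutoff: int = 20
    n_non_scd: int = 45
    n_scd: int = 50
    selection_sizes: dict[str, int] = field(
        default_factory=lambda: {"non-SCD": 24, "SCD": 26}
    )
    bands: tuple[str, ...] = ("delta", "theta")
    n_permutations: int = 2000
    mga_path: tuple[str, str] = ("personality", "memory_complaints")
    # network stage
    network_mode: str = "synthetic_adjacency"  # or "simulated_eeg"
    n_hubs_planted: int = 5
    hub_boost: float = 3.0
    base_density: float = 0.3
    rewiring_fraction: float = 0.25
    subject_jitter_sd: float = 0.03
    n_epochs: int = 40
    n_eeg_subjects_per_group: int | None = None  # None -> all selected subjects
    # siminet
    alpha: float = 0.5
    c_ins: float = 1.0
    epsilon: float = 0.0
    threshold_prop: float = 0.2

    def __post_init__(self) -> None:
        if self.cci_cutoff < 0:
            raise ValueError("cci_cutoff must be >= 0")
        if self.network_mode not in ("simulated_eeg", "synthetic_adjacency"):
            raise ValueError("unknown network_mode")
        sizes = {"non-SCD": self.n_non_scd, "SCD": self.n_scd}
        for group, k in self.selection_sizes.items():
            if group not in sizes:
                raise ValueError(f"unknown group {group!r} in selection_sizes")
            if k > sizes[group]:
                raise ValueError(
                    f"selection size {k} exceeds group size {sizes[group]} "
                    f"for group {group!r}"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "selection_sizes" in raw:
            raw["selection_sizes"] = dict(raw["selection_sizes"])
        if "bands" in raw:
            raw["bands"] = tuple(raw["bands"])
        if "mga_path" in raw:
            raw["mga_path"] = tuple(raw["mga_path"])
        return cls(**raw)


@dataclass(frozen=True)
class GroupComparison:
    """Two-group test of one variable with the normality gate recorded."""

    variable: str
    test: str  # "t-test" | "mann-whitney" | "degenerate"
    statistic: float
    p_value: float
    normal_a: bool
    normal_b: bool
    note: str | None = None


def assign_scd_group(cci_s_memory: float, cutoff: int = 20) -> str:
    """SCD iff the 12-item memory-complaint sum score is >= the cutoff."""
    if cci_s_memory < 0:
        raise ValueError("CCI-S memory score cannot be negative")
    return "SCD" if cci_s_memory >= cutoff else "non-SCD"


def select_middle_cohort(
    scores: pd.Series,
    groups: pd.Series,
    target_sizes: dict[str, int],
) -> list:
    """Middle-of-distribution subjects per group by symmetric tail trimming.

    Within each group, subjects are ranked by composite score and both
    tails are trimmed until the target size remains; when an odd number
    must go, the tail farther from the group median loses first.  Ties are
    resolved by stable subject-id order (deterministic, logged).
    """
    if not scores.index.equals(groups.index):
        raise ValueError("scores and groups must share the same subject index")
    selected = []
    for group, k in target_sizes.items():
        members = scores[groups == group]
        if k > len(members):
            raise ValueError(
                f"target size {k} exceeds group size {len(members)} for {group!r}"
            )
        ordered = members.sort_values(kind="mergesort")  # stable: id order on ties
        if ordered.index.has_duplicates:
            raise ValueError("subject ids must be unique")
        kept = list(ordered.items())
        median = float(np.median([v for _, v in kept]))
        while len(kept) > k:
            lo_id, lo_v = kept[0]
            hi_id, hi_v = kept[-1]
            if abs(hi_v - median) >= abs(lo_v - median):
                kept.pop()  # far (or tied) tail first, high side on exact ties
            else:
                kept.pop(0)
        selected.extend(sid for sid, _ in kept)
    return selected


def compare_groups(values: pd.Series, groups: pd.Series) -> GroupComparison:
    """t-test for normal samples, Mann-Whitney otherwise (two-tailed).

    Normality is assessed per group with Shapiro-Wilk at alpha = 0.05;
    the decision is recorded in the result.
    """
    labels = list(dict.fromkeys(groups))
    if len(labels) != 2:
        raise ValueError("exactly two groups are required")
    a = values[groups == labels[0]].to_numpy(float)
    b = values[groups == labels[1]].to_numpy(float)
    if min(a.size, b.size) < 3:
        raise ValueError("at least 3 subjects per group are required")
    name = values.name or "value"
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return GroupComparison(
            variable=name, test="degenerate", statistic=0.0, p_value=1.0,
            normal_a=False, normal_b=False,
            note="constant values in both groups",
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        normal_a = np.ptp(a) > 0 and stats.shapiro(a).pvalue > 0.05
        normal_b = np.ptp(b) > 0 and stats.shapiro(b).pvalue > 0.05
    if normal_a and normal_b:
        res = stats.ttest_ind(a, b)
        return GroupComparison(
            variable=name, test="t-test",
            statistic=float(res.statistic), p_value=float(res.pvalue),
            normal_a=True, normal_b=True,
        )
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(
        variable=name, test="mann-whitney",
        statistic=float(res.statistic), p_value=float(res.pvalue),
        normal_a=bool(normal_a), normal_b=bool(normal_b),
    )


# ----------------------------------------------------------------------
# full pipeline


def _study_model_spec() -> ModelSpec:
    target = "memory_complaints"
    spec = study_cohort_spec()
    return ModelSpec(
        constructs=[c.name for c in spec.constructs],
        indicator_map=spec.indicator_map,
        inner_paths=[
            ("neuropsych", target),
            ("emotional_distress", target),
            ("metacognitive_beliefs", target),
            ("personality", target),
        ],
    )


def _band_definitions(names) -> list[BandDefinition]:
    known = {"delta": DELTA, "theta": THETA}
    out = []
    for n in names:
        if n not in known:
            raise ValueError(f"unknown band {n!r}")
        out.append(known[n])
    return out


def _subject_matrix(
    template: ConnectivityMatrix,
    band: BandDefinition,
    config: PipelineConfig,
    subject_seed: int,
    subject_id: str,
) -> ConnectivityMatrix:
    """Per-subject network: jittered group template, optionally passed
    through the full source-simulation + connectivity route."""
    rng = np.random.default_rng(subject_seed)
    v = template.values.copy()
    jitter = rng.normal(0.0, config.subject_jitter_sd, size=v.shape)
    jitter = (jitter + jitter.T) / 2
    v = np.clip(v + (v > 0) * jitter, 0.0, 1.0)
    np.fill_diagonal(v, 0.0)
    target = ConnectivityMatrix(
        band=band.name, values=v, roi_order=template.roi_order,
        level="subject", subject_id=subject_id,
    )
    if config.network_mode == "synthetic_adjacency":
        return target
    epochs = generate_coupled_sources(
        target, band, n_epochs=config.n_epochs,
        subject_id=subject_id, seed=subject_seed,
    )
    return build_subject_adjacency(epochs, band)


def _comparison_dict(c: GroupComparison) -> dict:
    return {
        "variable": c.variable,
        "test": c.test,
        "statistic": round(c.statistic, 6),
        "p_value": round(c.p_value, 6),
        "normal_non_scd": c.normal_a,
        "normal_scd": c.normal_b,
    }


def run_full_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage on synthetic data and write the report bundle.

    Artifacts: cohort CSVs, measurement-diagnostics CSV, hub tables,
    Venn figures and a machine-readable ``summary.json`` that is
    byte-identical across runs with the same config and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    logger.info("pipeline start seed=%d", seed)

    # -- stage 1: cohort simulation + grouping by the memory cutoff
    cohort = generate_questionnaire_cohort(
        study_cohort_spec(seed=seed, n_non_scd=config.n_non_scd, n_scd=config.n_scd)
    )
    table = cohort.indicators.copy()
    table["group"] = [
        assign_scd_group(s, config.cci_cutoff) for s in table["CCIS_memory"]
    ]
    table.to_csv(out / "indicators.csv", index=False)
    cohort.construct_map.to_csv(out / "construct_map.csv", index=False)
    group_sizes = table["group"].value_counts().to_dict()
    logger.info("stage=grouping sizes=%s", group_sizes)

    # -- stage 2: descriptive group comparisons (Table-1 style)
    comparisons = []
    for col in cohort.spec.indicator_map:
        comparisons.append(
            compare_groups(table[col].rename(col), table["group"])
        )
    pd.DataFrame([_comparison_dict(c) for c in comparisons]).to_csv(
        out / "group_comparisons.csv", index=False
    )

    # -- stage 3: PLS path model per group + multigroup test
    model = _study_model_spec()
    data_a = table[table["group"] == "non-SCD"].reset_index(drop=True)
    data_b = table[table["group"] == "SCD"].reset_index(drop=True)
    fit_a = fit_pls_path_model(data_a, model)
    fit_b = fit_pls_path_model(data_b, model)
    mga = permutation_multigroup_test(
        data_a, data_b, model, config.mga_path,
        n_perm=config.n_permutations, seed=seed + 10,
    )
    _write_measurement_report(fit_a, out / "measurement_non_scd.csv")
    _write_measurement_report(fit_b, out / "measurement_scd.csv")

    # -- stage 4: pooled composite score and middle-cohort selection
    fit_all = fit_pls_path_model(table, model)
    composite = compute_composite_scores(fit_all, "memory_complaints")
    groups_by_id = pd.Series(table["group"].values, index=table["subject_id"])
    sel_sizes = {
        g: min(k, int(groups_by_id.value_counts().get(g, 0)))
        for g, k in config.selection_sizes.items()
    }
    selected = select_middle_cohort(composite, groups_by_id, sel_sizes)
    scatter = pd.DataFrame(
        {
            "subject_id": composite.index,
            "composite": composite.values,
            "group": groups_by_id.loc[composite.index].values,
            "selected": [sid in set(selected) for sid in composite.index],
        }
    )
    scatter.to_csv(out / "composite_scores.csv", index=False)
    comp_comparison = compare_groups(
        composite.rename("composite"), groups_by_id
    )

    # -- stage 5: per-band networks, similarity and hubs
    atlas = load_default_atlas()
    rng = np.random.default_rng(seed + 20)
    band_defs = _band_definitions(config.bands)
    selected_by_group = {
        g: [s for s in selected if groups_by_id[s] == g]
        for g in ("non-SCD", "SCD")
    }
    if config.n_eeg_subjects_per_group is not None:
        selected_by_group = {
            g: v[: config.n_eeg_subjects_per_group]
            for g, v in selected_by_group.items()
        }
    band_reports = {}
    for band_no, band in enumerate(band_defs):
        # partially overlapping hub sets: some hubs persist across groups,
        # others are lost/gained with the condition
        n_hubs = config.n_hubs_planted
        n_shared = max(1, n_hubs // 2)
        pool = [str(r) for r in rng.choice(
            atlas.roi_ids, size=2 * n_hubs - n_shared, replace=False
        )]
        hubs_a_ids = pool[:n_hubs]
        hubs_b_ids = pool[:n_shared] + pool[n_hubs:]
        net_spec = NetworkSpec(
            atlas=atlas,
            planted_hubs={
                "non-SCD": frozenset(hubs_a_ids),
                "SCD": frozenset(hubs_b_ids),
            },
            base_density=config.base_density,
            hub_boost=config.hub_boost,
            rewiring_fraction=config.rewiring_fraction,
            seed=seed + 100 + band_no,
        )
        templates = {
            g: generate_hub_network(net_spec, g, band=band.name)
            for g in ("non-SCD", "SCD")
        }
        subject_mats = {g: [] for g in templates}
        for g_no, (g, members) in enumerate(selected_by_group.items()):
            for i, sid in enumerate(members):
                subject_mats[g].append(
                    _subject_matrix(
                        templates[g], band, config,
                        subject_seed=seed + 7919 * (2 * band_no + g_no) + i + 1,
                        subject_id=sid,
                    )
                )
        avg = {g: group_average_adjacency(m) for g, m in subject_mats.items()}

        ref_graph = graph_from_adjacency(
            avg["non-SCD"], atlas, threshold_prop=config.threshold_prop
        )
        sims = []
        for m in subject_mats["SCD"]:
            g2 = graph_from_adjacency(m, atlas, threshold_prop=config.threshold_prop)
            sims.append(
                similarity_index(
                    ref_graph, g2, alpha=config.alpha,
                    epsilon=config.epsilon, c_ins=config.c_ins,
                    diameter=atlas.diameter(),
                ).index
            )

        hub_sets = {}
        for g in templates:
            bc = weighted_betweenness(avg[g])
            hub_sets[g] = detect_hubs(bc, group=g, band=band.name)
        partition = venn_partition(hub_sets["non-SCD"], hub_sets["SCD"])
        hub_table(list(hub_sets.values()), atlas).to_csv(
            out / f"hubs_{band.name}.csv", index=False
        )
        plot_venn(partition, ("non-SCD", "SCD"), out / f"venn_{band.name}.png")

        band_reports[band.name] = {
            "similarity_mean": round(float(np.mean(sims)), 6),
            "similarity_sd": round(float(np.std(sims, ddof=1)), 6) if len(sims) > 1 else 0.0,
            "n_similarity": len(sims),
            "n_hubs_non_scd": len(hub_sets["non-SCD"].hubs),
            "n_hubs_scd": len(hub_sets["SCD"].hubs),
            "venn": {
                "shared": partition.counts[0],
                "non_scd_only": partition.counts[1],
                "scd_only": partition.counts[2],
            },
            "planted_hubs": {
                "non-SCD": sorted(hubs_a_ids),
                "SCD": sorted(hubs_b_ids),
            },
        }
        logger.info(
            "stage=network band=%s venn=%s", band.name, band_reports[band.name]["venn"]
        )

    summary = {
        "seed": seed,
        "config_digest": hashlib.sha256(
            json.dumps(str(config), sort_keys=True).encode()
        ).hexdigest()[:16],
        "group_sizes": {k: int(v) for k, v in sorted(group_sizes.items())},
        "paths": {
            "non-SCD": {f"{a}->{b}": round(v, 6) for (a, b), v in sorted(fit_a.path_coefficients.items())},
            "SCD": {f"{a}->{b}": round(v, 6) for (a, b), v in sorted(fit_b.path_coefficients.items())},
        },
        "r_squared": {
            "non-SCD": {k: round(v, 6) for k, v in fit_a.r_squared.items()},
            "SCD": {k: round(v, 6) for k, v in fit_b.r_squared.items()},
        },
        "mga": {
            "path": "->".join(mga.path),
            "observed_diff": round(mga.observed_diff, 6),
            "p_value": round(mga.p_value, 6),
            "n_permutations": mga.n_permutations,
        },
        "composite": _comparison_dict(comp_comparison),
        "selection": {g: len(v) for g, v in selected_by_group.items()},
        "bands": band_reports,
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary


def _write_measurement_report(fit, path: Path) -> None:
    """Loadings / cross-loadings with rho_c and AVE, one row per indicator."""
    cross = fit.cross_loadings.copy()
    cross.insert(0, "construct", [fit.model.indicator_map[i] for i in cross.index])
    cross["rho_c"] = [fit.rho_c[c] for c in cross["construct"]]
    cross["ave"] = [fit.ave[c] for c in cross["construct"]]
    cross.round(6).to_csv(path, index_label="indicator")
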