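"""Full study orchestration.

For each of the six inputs (three groups x SC/FC) the pipeline builds graphs
by every requested construction scheme, computes the minimum driver set,
the critical nodes, and both spectral robustness measures, and summarizes
the results per group.  Percentage-threshold cutoffs are derived once from
the reference (control) group per modality and fraction, then applied to
every group — the study's comparison convention — and the driver count is
additionally averaged over the five canonical fractions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .construction import (
    STUDY_FRACTIONS,
    DisconnectedGraphError,
    ThresholdSpec,
    adaptive_threshold,
    chow_liu_tree,
    partial_correlation_graph,
    percentage_threshold,
)
from .controllability import (
    CriticalNodeResult,
    DriverResult,
    critical_nodes,
    identify_drivers,
)
from .io_formats import (
    BinaryGraph,
    ConnectivityMatrix,
    read_connectivity_matrix,
    write_connectivity_matrix,
    write_report,
)
from .robustness import RobustnessReport, robustness_report
from .synthetic import GROUPS, GeneratorConfig, generate_study_set

__all__ = [
    "StudyConfig",
    "GroupReport",
    "run_study",
    "summary_table",
    "shared_and_alternative_nodes",
    "make_figures",
    "load_study_inputs",
    "write_study_inputs",
    "study_report",
]

log = logging.getLogger(__name__)

MODALITIES = ("SC", "FC")


class ConfigurationError(ValueError):
    """The study configuration is inconsistent with the available inputs."""


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to run the study end to end.

    Inputs come either from a synthetic ``generator`` config or from
    ``input_dir`` holding ``{group}_{modality}.csv`` matrices with JSON
    sidecars.  ``per_graph_cutoffs`` switches percentage thresholding from
    control-derived cutoffs (the default comparison convention) to cutoffs
    derived from each matrix itself, for sensitivity analysis.
    """

    generator: Optional[GeneratorConfig] = None
    input_dir: Optional[str] = None
    methods: tuple[str, ...] = ("percentage", "adaptive", "pcm", "chowliu")
    percentage_fractions: tuple[float, ...] = STUDY_FRACTIONS
    reference_group: str = "control"
    per_graph_cutoffs: bool = False
    soft_threshold: float = 0.1
    adaptive_tolerance: float = 1e-4
    critical_fraction: float = 0.30
    tol: Optional[float] = None

    def __post_init__(self) -> None:
        if self.generator is None and self.input_dir is None:
            object.__setattr__(self, "generator", GeneratorConfig())
        object.__setattr__(
            self, "percentage_fractions", tuple(float(f) for f in self.percentage_fractions)
        )
        object.__setattr__(self, "methods", tuple(self.methods))
        unknown = set(self.methods) - {"percentage", "adaptive", "pcm", "chowliu"}
        if unknown:
            raise ConfigurationError(f"unknown methods {sorted(unknown)}")
        if not self.percentage_fractions and "percentage" in self.methods:
            raise ConfigurationError("percentage method requested without fractions")

    @classmethod
    def from_dict(cls, data: Mapping) -> "StudyConfig":
        data = dict(data)
        gen = data.pop("generator", None)
        if gen is not None:
            gen = GeneratorConfig(**gen)
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        extra = set(data) - known
        if extra:
            raise ConfigurationError(f"unknown study-config keys {sorted(extra)}")
        return cls(generator=gen, **data)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass(frozen=True)
class GroupReport:
    """All per-method results for one group x modality."""

    group: str
    modality: str
    labels: tuple[int, ...]
    methods: dict  # method name -> {"graph": {...}, "drivers": DriverResult, ...}
    driver_counts_by_fraction: dict[float, int]
    average_driver_count: float

    def key(self) -> str:
        return f"{self.group}/{self.modality}"

    def driver_set(self, method: str) -> set[int]:
        return set(self.methods[method]["drivers"].drivers)

    def critical_set(self, method: str) -> set[int]:
        return set(self.methods[method]["critical"].critical)

    def to_dict(self) -> dict:
        methods = {}
        for name, entry in self.methods.items():
            methods[name] = {
                "graph": dict(entry["graph"]),
                "drivers": entry["drivers"].to_dict(),
                "critical": entry["critical"].to_dict(),
                "robustness": entry["robustness"].to_dict(),
            }
        return {
            "group": self.group,
            "modality": self.modality,
            "labels": list(self.labels),
            "driver_counts_by_fraction": {
                f"{f:g}": c for f, c in sorted(self.driver_counts_by_fraction.items())
            },
            "average_driver_count": self.average_driver_count,
            "methods": methods,
        }


def _graph_summary(graph: BinaryGraph) -> dict:
    return {
        "n_nodes": graph.n_nodes,
        "n_edges": graph.n_edges,
        **{k: v for k, v in graph.provenance.items()},
    }


def _analyze(graph: BinaryGraph, tol) -> dict:
    return {
        "graph": _graph_summary(graph),
        "drivers": identify_drivers(graph, tol=tol),
        "critical": critical_nodes(graph, tol=tol),
        "robustness": robustness_report(graph),
        "_graph_obj": graph,
    }


def load_study_inputs(input_dir, groups: Sequence[str] = GROUPS
                      ) -> dict[tuple[str, str], ConnectivityMatrix]:
    """Read ``{group}_{modality}.csv`` + ``.json`` pairs from a directory."""
    input_dir = Path(input_dir)
    found = sorted(p.name for p in input_dir.glob("*.csv"))
    out = {}
    missing = []
    for group in groups:
        for modality in MODALITIES:
            stem = input_dir / f"{group}_{modality}"
            if not stem.with_suffix(".csv").exists():
                missing.append(f"{group}_{modality}.csv")
                continue
            out[(group, modality)] = read_connectivity_matrix(
                stem.with_suffix(".csv"), stem.with_suffix(".json")
            )
    if missing:
        raise ConfigurationError(
            f"missing inputs {missing} in {input_dir} (found: {found})"
        )
    return out


def write_study_inputs(matrices: Mapping[tuple[str, str], ConnectivityMatrix],
                       output_dir) -> None:
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    for (group, modality), m in matrices.items():
        stem = output_dir / f"{group}_{modality}"
        write_connectivity_matrix(m, stem.with_suffix(".csv"), stem.with_suffix(".json"))


def run_study(config: StudyConfig) -> dict[tuple[str, str], GroupReport]:
    """Run every requested construction scheme and analysis for all inputs.

    Returns one GroupReport per (group, modality).  Fully deterministic
    given the config (and its generator seed).
    """
    if config.input_dir is not None:
        matrices = load_study_inputs(config.input_dir)
        groups = GROUPS
    else:
        matrices = generate_study_set(config.generator)
        groups = config.generator.groups()

    present = set(matrices)
    wanted = {(g, m) for g in groups for m in MODALITIES}
    if wanted - present:
        raise ConfigurationError(
            f"missing inputs {sorted(wanted - present)}; found {sorted(present)}"
        )
    if config.reference_group not in groups:
        raise ConfigurationError(
            f"reference group {config.reference_group!r} not among {groups}"
        )

    reports: dict[tuple[str, str], GroupReport] = {}
    for modality in MODALITIES:
        ref = matrices[(config.reference_group, modality)]
        for group in groups:
            m = matrices[(group, modality)]
            methods: dict[str, dict] = {}
            counts: dict[float, int] = {}
            avg = float("nan")

            if "percentage" in config.methods:
                prev_edges = None
                graph_at_critical = None
                for frac in config.percentage_fractions:
                    spec = ThresholdSpec(
                        method="percentage",
                        fraction=frac,
                        reference=None if config.per_graph_cutoffs else ref,
                    )
                    g = percentage_threshold(m, spec)
                    if prev_edges is not None and g.n_edges > prev_edges:
                        raise AssertionError(
                            "edge count increased along the threshold sweep"
                        )
                    prev_edges = g.n_edges
                    dres = identify_drivers(g, tol=config.tol)
                    counts[frac] = dres.count
                    log.info(
                        "%s/%s percentage f=%.3g cutoff=%.6g edges=%d "
                        "lambda_M=%.6g mult=%d",
                        group, modality, frac, g.provenance["cutoff"],
                        g.n_edges, dres.eigenvalue_used, dres.multiplicity,
                    )
                    if abs(frac - config.critical_fraction) < 1e-12:
                        graph_at_critical = g
                if graph_at_critical is None:
                    graph_at_critical = g  # fall back to the last fraction
                avg = float(np.mean(list(counts.values())))
                methods["percentage"] = _analyze(graph_at_critical, config.tol)

            if "adaptive" in config.methods:
                g, cutoff = adaptive_threshold(
                    m, ThresholdSpec(method="adaptive",
                                     tolerance=config.adaptive_tolerance)
                )
                log.info("%s/%s adaptive cutoff=%.6g edges=%d",
                         group, modality, cutoff, g.n_edges)
                methods["adaptive"] = _analyze(g, config.tol)

            if "pcm" in config.methods and modality == "FC":
                g = partial_correlation_graph(
                    m, ThresholdSpec(method="pcm",
                                     soft_threshold=config.soft_threshold)
                )
                methods["pcm"] = _analyze(g, config.tol)

            if "chowliu" in config.methods:
                g = chow_liu_tree(m)
                methods["chowliu"] = _analyze(g, config.tol)

            reports[(group, modality)] = GroupReport(
                group=group,
                modality=modality,
                labels=m.labels.labels,
                methods=methods,
                driver_counts_by_fraction=counts,
                average_driver_count=avg,
            )
    return reports


def summary_table(reports: Mapping[tuple[str, str], GroupReport]) -> pd.DataFrame:
    """Cross-group summary: one row per (group, modality)."""
    rows = []
    for (group, modality), r in reports.items():
        row = {
            "group": group,
            "modality": modality,
            "average_driver_count": r.average_driver_count,
        }
        for name, entry in r.methods.items():
            row[f"{name}_drivers"] = entry["drivers"].count
            row[f"{name}_critical"] = len(entry["critical"].critical)
            row[f"{name}_algebraic"] = entry["robustness"].algebraic
            row[f"{name}_natural"] = entry["robustness"].natural
            row[f"{name}_edges"] = entry["graph"]["n_edges"]
        rows.append(row)
    return pd.DataFrame(rows).set_index(["group", "modality"]).sort_index()


def shared_and_alternative_nodes(
    reports: Mapping[tuple[str, str], GroupReport],
    node_kind: str = "driver",
    control_group: str = "control",
) -> dict[tuple[str, str], dict]:
    """Set comparison of driver or critical nodes across groups.

    For each (modality, method): the intersection across all groups
    ("common"), and per patient group the nodes present in the patient but
    not the control ("alternative") and present in the control but not the
    patient ("lost").  All node sets are ROI labels.
    """
    if node_kind not in ("driver", "critical"):
        raise ValueError("node_kind must be 'driver' or 'critical'")
    by_mod: dict[str, dict[str, GroupReport]] = {}
    label_sets = {tuple(r.labels) for r in reports.values()}
    if len(label_sets) > 1:
        raise ValueError("reports carry mismatched ROI label sets")
    for (group, modality), r in reports.items():
        by_mod.setdefault(modality, {})[group] = r

    def node_set(r: GroupReport, method: str) -> set[int]:
        return r.driver_set(method) if node_kind == "driver" else r.critical_set(method)

    out: dict[tuple[str, str], dict] = {}
    for modality, per_group in by_mod.items():
        if control_group not in per_group:
            raise ValueError(f"control group {control_group!r} missing for {modality}")
        methods = set.intersection(*(set(r.methods) for r in per_group.values()))
        for method in sorted(methods):
            if len(per_group) < 2:
                continue
            sets = {g: node_set(r, method) for g, r in per_group.items()}
            common = set.intersection(*sets.values())
            entry: dict = {"common": sorted(common), "groups": {}}
            ctrl = sets[control_group]
            for g, s in sets.items():
                if g == control_group:
                    continue
                entry["groups"][g] = {
                    "alternative": sorted(s - ctrl),
                    "lost": sorted(ctrl - s),
                }
            out[(modality, method)] = entry
    return out


def study_report(reports: Mapping[tuple[str, str], GroupReport], path) -> None:
    """Write the full study report as a single JSON document."""
    write_report({r.key(): r.to_dict() for r in reports.values()}, path)


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

def make_figures(reports: Mapping[tuple[str, str], GroupReport], output_dir,
                 seed: int = 0) -> list[Path]:
    """Per-group graph drawings plus the two cross-group summary charts.

    Drivers are highlighted in red and critical nodes in green, matching the
    study's figure conventions; layouts are seeded so repeated runs produce
    identical files.  Returns the written paths.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    import networkx as nx

    output_dir = Path(output_dir)
    if not reports:
        warnings.warn("no reports: no figures written", RuntimeWarning, stacklevel=2)
        return []
    output_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for (group, modality), r in sorted(reports.items()):
        method = "percentage" if "percentage" in r.methods else next(iter(r.methods))
        entry = r.methods[method]
        graph: BinaryGraph = entry["_graph_obj"]
        drivers = set(entry["drivers"].drivers)
        critical = set(entry["critical"].critical)
        g = graph.to_networkx()
        pos = nx.spring_layout(g, seed=seed)
        colors = [
            "tab:red" if n in drivers else
            "tab:green" if n in critical else "lightgray"
            for n in g.nodes
        ]
        fig, ax = plt.subplots(figsize=(6, 6))
        nx.draw_networkx(g, pos=pos, ax=ax, node_color=colors, node_size=320,
                         font_size=7, edge_color="silver")
        ax.set_title(
            f"{group} {modality} [{method}] — drivers red, critical green"
        )
        ax.axis("off")
        path = output_dir / f"graph_{group}_{modality}.png"
        fig.savefig(path, dpi=120, metadata={"Software": "connectoctrl"})
        plt.close(fig)
        written.append(path)

    # driver counts per threshold fraction
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, modality in zip(axes, MODALITIES):
        sub = {g: r for (g, m), r in reports.items() if m == modality}
        fractions = sorted({f for r in sub.values()
                            for f in r.driver_counts_by_fraction})
        width = 0.8 / max(len(sub), 1)
        for i, (group, r) in enumerate(sorted(sub.items())):
            y = [r.driver_counts_by_fraction.get(f, np.nan) for f in fractions]
            ax.bar(np.arange(len(fractions)) + i * width, y, width, label=group)
        ax.set_xticks(np.arange(len(fractions)) + 0.4 - width / 2)
        ax.set_xticklabels([f"{f:g}" for f in fractions])
        ax.set_xlabel("removed fraction")
        ax.set_title(modality)
    axes[0].set_ylabel("driver count")
    axes[0].legend()
    path = output_dir / "drivers_by_threshold.png"
    fig.savefig(path, dpi=120, metadata={"Software": "connectoctrl"})
    plt.close(fig)
    written.append(path)

    # robustness per method
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, modality in zip(axes, MODALITIES):
        sub = {g: r for (g, m), r in reports.items() if m == modality}
        methods = sorted({name for r in sub.values() for name in r.methods})
        width = 0.8 / max(len(sub), 1)
        for i, (group, r) in enumerate(sorted(sub.items())):
            y = [r.methods[name]["robustness"].algebraic if name in r.methods
                 else np.nan for name in methods]
            ax.bar(np.arange(len(methods)) + i * width, y, width, label=group)
        ax.set_xticks(np.arange(len(methods)) + 0.4 - width / 2)
        ax.set_xticklabels(methods)
        ax.set_title(f"{modality}: algebraic connectivity")
    axes[0].legend()
    path = output_dir / "robustness_by_method.png"
    fig.savefig(path, dpi=120, metadata={"Software": "connectoctrl"})
    plt.close(fig)
    written.append(path)
    return written
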