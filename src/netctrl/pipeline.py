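"""End-to-end analysis: reaction list -> full controllability report.

Stages: build the network, sample driver sets and classify driver
frequencies, exact node control classes and control mode, link
robustness classes and reaction-class enrichment (with a chi-square test
of the critical-link composition against the whole-network composition),
modules and roles via simulated annealing, centrality tertile profiles
of the driver sets (with per-centrality chi-square tests), all written
as TSV tables plus one JSON summary carrying every seed and count needed
to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import centrality as _centrality
from . import controllability as _ctrl
from . import link_classes as _links
from . import modularity_roles as _mod
from . import stats as _stats
from .reaction_io import (
    MetaboliteNetwork,
    build_network,
    link_annotation_table,
    parse_reactions,
)

__all__ = ["RunConfig", "run_full_analysis"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Exactly one of ``reactions_path`` / ``network_path`` must be set;
    annotation-dependent stages (link enrichment) are skipped for bare
    edge lists.  Defaults: 5000 matching samples, driver-frequency
    thresholds 1.0 / 0.6, SA with f = 1 and c = 0.965, alpha = 0.05.
    """

    reactions_path: str | None = None
    network_path: str | None = None
    out_dir: str = "netctrl_out"
    n_samples: int = 5000
    alpha: float = 0.05
    seed: int = 0
    extracellular: str = "e"
    closeness_variant: str = "harmonic"
    sa: _mod.SAConfig = field(default_factory=_mod.SAConfig)
    role_thresholds: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(10))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sa = _mod.SAConfig(**raw.pop("sa", {}))
        if "role_thresholds" in raw:
            raw["role_thresholds"] = tuple(raw["role_thresholds"])
        return cls(sa=sa, **raw)


def _json_default(obj: Any):
    import fractions

    if isinstance(obj, fractions.Fraction):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the summary.

    Idempotent for a fixed config: all randomness is derived from
    ``config.seed``.
    """
    if (config.reactions_path is None) == (config.network_path is None):
        raise ValueError("set exactly one of reactions_path / network_path")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"config": _config_dict(config)}

    # -- stage: build -------------------------------------------------
    annotations = None
    try:
        if config.reactions_path:
            reactions = parse_reactions(Path(config.reactions_path))
            network = build_network(reactions)
            annotations = link_annotation_table(
                network, reactions, extracellular=config.extracellular
            )
            summary["model"] = {
                "n_reactions": len(reactions),
                "n_transport_reactions": sum(r.is_transport for r in reactions),
            }
        else:
            network = MetaboliteNetwork.from_edgelist(Path(config.network_path))
        (out / "network.edgelist").write_text(network.to_edgelist())
        summary["network"] = {
            "n_nodes": network.n_nodes,
            "n_links": network.n_links,
            "n_self_loops": len(network.self_loops),
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'build' failed: {exc}") from exc

    # -- stage: drivers -----------------------------------------------
    try:
        sample = _ctrl.sample_mdms(network, config.n_samples, seed=config.seed)
        freq = _ctrl.driver_frequency(sample, nodes=network.nodes)
        freq.as_frame().to_csv(out / "drivers.tsv", sep="\t")
        cls_counts = pd.Series(freq.classes).value_counts().to_dict()
        summary["drivers"] = {
            "seed": config.seed,
            "n_samples_requested": config.n_samples,
            "n_distinct_matchings": sample.n_distinct_matchings,
            "n_distinct_mdms": len(sample),
            "matching_size": sample.matching_size,
            "mdms_size": len(sample[0]) if len(sample) else 0,
            "class_counts": cls_counts,
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'drivers' failed: {exc}") from exc

    # -- stage: control mode ------------------------------------------
    try:
        mode = _ctrl.control_mode(network)
        summary["control_mode"] = {
            "n_r": float(mode.n_r),
            "n_r_T": float(mode.n_r_T),
            "delta_n_r": float(mode.delta_n_r),
            "mode": mode.mode,
            "n_critical_nodes": sum(
                1 for c in mode.node_class.values() if c == "critical"
            ),
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'control_mode' failed: {exc}") from exc

    # -- stage: link classes ------------------------------------------
    try:
        table = _links.classify_links(network, seed=config.seed)
        frame = table.as_frame()
        if annotations is not None:
            enrich = _links.link_class_enrichment(table, annotations)
            enrich.to_csv(out / "link_enrichment.tsv", sep="\t")
            observed = [
                int(enrich.loc["critical", f"count_{rc}"])
                for rc in ("core_high", "core_moderate", "non_core")
            ]
            expected = [
                float(enrich.loc["ensemble", f"frac_{rc}"])
                for rc in ("core_high", "core_moderate", "non_core")
            ]
            chisq = None
            if min(observed) >= 0 and sum(observed) > 0 and min(expected) > 0:
                total = sum(expected)
                res = _stats.chi_square(
                    observed, [p / total for p in expected], alpha=config.alpha
                )
                chisq = {
                    "statistic": res.statistic,
                    "df": res.df,
                    "critical_value": res.critical_value,
                    "significant": res.significant,
                }
            summary["link_enrichment_chi_square"] = chisq
            frame = frame.join(annotations[["is_transport", "crosses_into_cell"]])
        frame.to_csv(out / "links.tsv", sep="\t")
        summary["link_classes"] = table.counts
    except Exception as exc:
        raise RuntimeError(f"stage 'links' failed: {exc}") from exc

    # -- stage: modules and roles -------------------------------------
    try:
        sa_cfg = dataclasses.replace(config.sa, seed=config.sa.seed if config.sa.seed is not None else config.seed)
        part = _mod.simulated_annealing(network, sa_cfg)
        part.as_frame().to_csv(out / "modules.tsv", sep="\t")
        roles = _mod.assign_roles(network, part)
        roles.table.to_csv(out / "roles.tsv", sep="\t")
        profile = _mod.driver_role_profile(roles, freq, config.role_thresholds)
        profile.to_csv(out / "driver_role_profile.tsv", sep="\t")
        role_counts = roles.table["role"].value_counts().to_dict()
        summary["modules"] = {
            "seed": sa_cfg.seed,
            "n_modules": part.n_modules,
            "modularity": part.modularity,
            "role_counts": {k: int(v) for k, v in role_counts.items()},
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'modules' failed: {exc}") from exc

    # -- stage: centrality profiles ------------------------------------
    try:
        cent = _centrality.compute_centralities(network, config.closeness_variant)
        cent.to_csv(out / "centrality.tsv", sep="\t")
        families = {
            col: _centrality.tertile_split(cent[col].to_dict())
            for col in _centrality.CENTRALITY_COLUMNS
        }
        set_a = sorted({n for s in sample for n in s})
        classes = freq.classes
        set_b = sorted(
            n for n, c in classes.items() if c in ("critical", "high_frequency")
        )
        summary["driver_sets"] = {"set_A_size": len(set_a), "set_B_size": len(set_b)}
        profiles: dict[str, Any] = {}
        for name, node_set in (("A", set_a), ("B", set_b)):
            if not node_set:
                profiles[name] = None
                continue
            prof = _centrality.fraction_profile(node_set, families)
            prof.to_csv(out / f"profile_set_{name}.tsv", sep="\t")
            tests = {}
            n_all = network.n_nodes
            for col, fam in families.items():
                expected = [len(s) / n_all for s in fam.sets()]
                observed = [
                    int(prof.loc[col, f"count_{b}"]) for b in ("low", "medium", "high")
                ]
                if min(expected) <= 0:
                    tests[col] = None
                    continue
                res = _stats.chi_square(observed, expected, alpha=config.alpha)
                tests[col] = {
                    "statistic": res.statistic,
                    "df": res.df,
                    "critical_value": res.critical_value,
                    "significant": res.significant,
                }
            profiles[name] = tests
        summary["centrality_chi_square"] = profiles
    except Exception as exc:
        raise RuntimeError(f"stage 'centrality' failed: {exc}") from exc

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_json_default) + "\n"
    )
    return summary


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["role_thresholds"] = list(config.role_thresholds)
    return d
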