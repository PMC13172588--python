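"""End-to-end synthetic-study pipeline.

Orchestrates simulate -> motif scan -> translation efficiency ->
enrichment -> trajectory clustering on one run directory, with a manifest
recording the configuration, every seed and threshold actually used, and
SHA-256 hashes of all outputs. Re-running with an identical configuration
reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.distance import pdist, squareform

from . import __version__
from .enrichment_stats import contingency_test, intersect3, ora_test, rank_test
from .io import read_gmt, write_study
from .motif_scan import bin_summary, profiles_to_frame, scan_motifs
from .synthetic_data import SimConfig, generate_study
from .trajectory_cluster import (
    choose_k_elbow,
    fuzzy_cmeans,
    intersect_cohorts,
    permanova,
    select_monotone_cluster,
    zscore_profiles,
)
from .translation_efficiency import compute_te, differential_te, min_count_mask

__all__ = ["PipelineError", "default_config", "load_config", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def default_config() -> dict[str, Any]:
    return {
        "seed": 0,
        "sim": {},
        "te": {
            "control": "control",
            "treated": "treated",
            "pseudocount": 1.0,
            "lfc_threshold": 1.5,
            "alpha": 0.05,
            "min_mean_rna": 5.0,
        },
        "enrichment": {
            "pp_source": "altered",
            "top": 5,
            # optional external gene-set inputs; defaults use the simulated sets
            "metastasis_gmt": None,
            "pathways_gmt": None,
        },
        "cluster": {
            "k": "auto",
            "k_min": 2,
            "k_max": 8,
            "m": 2.0,
            "n_starts": 10,
            "min_membership": 0.5,
            "direction": "increasing",
        },
        "permanova": {"n_permutations": 999},
    }


def load_config(path) -> dict[str, Any]:
    """YAML config merged over the defaults (one level deep)."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    for key, value in user.items():
        if isinstance(value, Mapping) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _euclidean(x: np.ndarray) -> np.ndarray:
    return squareform(pdist(x, metric="euclidean"))


def run_pipeline(config: Mapping[str, Any] | str | Path, out_dir) -> dict[str, Any]:
    """Run every stage into ``out_dir``; returns the manifest dict.

    ``config`` is a config dict (see :func:`default_config`) or a YAML
    path. On a stage failure a ``FAILED_<stage>`` marker is written next
    to whatever partial outputs exist and a :class:`PipelineError` naming
    the stage is raised.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else {
        **default_config(), **{k: v for k, v in config.items()}
    }
    if isinstance(config, Mapping):
        for key in ("sim", "te", "enrichment", "cluster", "permanova"):
            if key in config:
                merged = default_config()[key]
                merged.update(config[key])
                cfg[key] = merged

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    outputs: dict[str, str] = {}
    stage = "setup"

    def _write_df(df: pd.DataFrame, rel: str, index: bool = True) -> None:
        path = out / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        sep = "\t" if rel.endswith(".tsv") else ","
        df.to_csv(path, sep=sep, index=index)
        outputs[rel] = ""

    try:
        # --- simulate -----------------------------------------------------
        stage = "simulate"
        sim_cfg = SimConfig(**{**cfg.get("sim", {}), "seed": seed})
        study = generate_study(sim_cfg)
        for name, path in write_study(study, out / "sim").items():
            outputs[str(Path(path).relative_to(out))] = ""

        # --- motif scan ---------------------------------------------------
        stage = "motifs"
        profiles = [scan_motifs(r.sequence, gene=r.gene) for r in study.proteome]
        motif_df = profiles_to_frame(profiles).set_index("gene")
        _write_df(motif_df, "motifs/motifs.tsv")
        _write_df(bin_summary(profiles), "motifs/bin_summary.tsv", index=False)

        # --- translation efficiency ----------------------------------------
        stage = "te"
        te_cfg = cfg["te"]
        te = compute_te(study.counts, pseudocount=te_cfg["pseudocount"])
        tested = min_count_mask(study.counts, te_cfg["min_mean_rna"])
        de = differential_te(
            te,
            control=te_cfg["control"],
            treated=te_cfg["treated"],
            lfc_threshold=te_cfg["lfc_threshold"],
            alpha=te_cfg["alpha"],
            tested=tested,
        )
        _write_df(de, "te/te_results.tsv")
        scatter = de[["mean_log2_te_control", "mean_log2_te_treated", "log2fc", "class"]]
        _write_df(scatter, "te/te_scatter.tsv")

        # --- enrichment -----------------------------------------------------
        stage = "enrichment"
        en_cfg = cfg["enrichment"]
        metastasis_set = study.gene_sets["metastasis"]
        pathways = {k: v for k, v in study.gene_sets.items() if k != "metastasis"}
        for key, target in (("metastasis_gmt", "metastasis"), ("pathways_gmt", "pathways")):
            gmt_path = en_cfg.get(key)
            if gmt_path is not None:
                if not Path(gmt_path).exists():
                    raise FileNotFoundError(f"missing input {key}: {gmt_path}")
                loaded = read_gmt(gmt_path)
                if target == "metastasis":
                    metastasis_set = frozenset().union(*loaded.values())
                else:
                    pathways = loaded
        tested_genes = de.index[de["tested"]]
        down = set(de.index[de["class"] == "down"])
        up = set(de.index[de["class"] == "up"])
        pp_genes = set(motif_df.index[motif_df["pp_count"] >= 1])

        # PP-containing vs PP-free, TE-down vs other tested genes
        other = set(tested_genes) - down
        table = [
            [len(down & pp_genes), len(down - pp_genes)],
            [len(other & pp_genes), len(other - pp_genes)],
        ]
        stat, p = contingency_test(table, method="auto")
        rows = [("pp_down_vs_rest", "chi2_or_fisher", stat, p)]
        if up and down:
            u, p_mw = rank_test(
                motif_df.loc[sorted(up), "pp_count"].to_numpy(),
                motif_df.loc[sorted(down), "pp_count"].to_numpy(),
            )
            rows.append(("pp_count_up_vs_down", "mann_whitney", u, p_mw))
        _write_df(
            pd.DataFrame(rows, columns=["comparison", "test", "statistic", "p_value"]),
            "enrichment/association_tests.tsv",
            index=False,
        )

        altered = down | up
        pp_source = altered & pp_genes if en_cfg["pp_source"] == "altered" else pp_genes
        venn = intersect3(
            metastasis_set, down, pp_source,
            names=("metastasis", "te_down", "pp_containing"),
        )
        candidates = list(venn.common)
        (out / "enrichment").mkdir(exist_ok=True)
        (out / "enrichment/venn.json").write_text(
            json.dumps({"names": venn.names, "regions": venn.regions,
                        "common": candidates}, indent=1)
        )
        outputs["enrichment/venn.json"] = ""
        (out / "enrichment/candidates.txt").write_text("\n".join(candidates) + "\n")
        outputs["enrichment/candidates.txt"] = ""

        query = candidates if candidates else sorted(down)
        ora = ora_test(query, pathways, universe=tested_genes)
        _write_df(ora, "enrichment/ora.tsv", index=False)

        # --- trajectory clustering ------------------------------------------
        stage = "trajectory"
        cl_cfg = cfg["cluster"]
        members_by_cohort: dict[str, set[str]] = {}
        perm_rows = []
        for cohort, panel in study.panels.items():
            z, _flat = zscore_profiles(panel.values)
            if cl_cfg["k"] == "auto":
                k, curve = choose_k_elbow(
                    z, range(cl_cfg["k_min"], cl_cfg["k_max"] + 1),
                    m=cl_cfg["m"], seed=seed, n_starts=cl_cfg["n_starts"],
                )
                _write_df(curve, f"trajectory/{cohort}_objective_curve.tsv", index=False)
            else:
                k = int(cl_cfg["k"])
            model = fuzzy_cmeans(z, k, m=cl_cfg["m"], seed=seed, n_starts=cl_cfg["n_starts"])
            _write_df(model.memberships, f"trajectory/{cohort}_memberships.tsv")
            _write_df(
                pd.DataFrame(model.centers, columns=panel.groups),
                f"trajectory/{cohort}_centers.tsv",
            )
            members = select_monotone_cluster(
                model, direction=cl_cfg["direction"],
                min_membership=cl_cfg["min_membership"],
            )
            members_by_cohort[cohort] = members
            (out / f"trajectory/{cohort}_{cl_cfg['direction']}_members.txt").write_text(
                "\n".join(sorted(members)) + "\n"
            )
            outputs[f"trajectory/{cohort}_{cl_cfg['direction']}_members.txt"] = ""

            if panel.replicate_values is not None:
                x = panel.replicate_values.to_numpy(dtype=float)
                x = (x - x.mean(axis=0)) / np.where(x.std(axis=0) == 0, 1, x.std(axis=0))
                res = permanova(
                    _euclidean(x), panel.replicate_groups.to_numpy(),
                    n_permutations=cfg["permanova"]["n_permutations"], seed=seed,
                )
                perm_rows.append(
                    (cohort, res.f_statistic, res.r_squared, res.p_value, res.n_permutations)
                )

        common = intersect_cohorts(members_by_cohort)
        (out / "trajectory/intersection.txt").write_text("\n".join(common) + "\n")
        outputs["trajectory/intersection.txt"] = ""
        if perm_rows:
            _write_df(
                pd.DataFrame(
                    perm_rows,
                    columns=["cohort", "pseudo_F", "r_squared", "p_value", "n_permutations"],
                ),
                "trajectory/permanova.tsv",
                index=False,
            )

        # --- manifest --------------------------------------------------------
        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": seed,
            "config": {k: v for k, v in cfg.items() if k != "sim"},
            "sim_config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in sim_cfg.__dict__.items()
                if not isinstance(v, Mapping)
            },
            "outputs": {rel: _sha256(out / rel) for rel in sorted(outputs)},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest
    except Exception as exc:  # noqa: BLE001 - stage context is the point
        (out / f"FAILED_{stage}").write_text(str(exc))
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
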