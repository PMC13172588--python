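"""Readers and writers for the plain-text formats used across the pipeline.

Formats: protein FASTA, gene x sample counts TSV (header row = sample ids),
sample-metadata CSV, metabolite panel CSV (first column metabolite,
remaining columns the ordered groups), GMT gene-set collections, and the
truth/manifest JSON files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd

from .enrichment_stats import GeneSetCollection
from .synthetic_data import ProteomeRecord, SyntheticStudy
from .trajectory_cluster import MetabolitePanel
from .translation_efficiency import CountsExperiment

__all__ = [
    "write_fasta",
    "read_gmt",
    "write_gmt",
    "write_counts",
    "read_counts",
    "write_panel",
    "read_panel",
    "write_study",
]


def write_fasta(records: Iterable[ProteomeRecord] | Iterable[tuple[str, str]], path) -> None:
    """Write ``>geneID`` FASTA, 60 columns per line."""
    with open(path, "w") as fh:
        for rec in records:
            gene, seq = (rec.gene, rec.sequence) if isinstance(rec, ProteomeRecord) else rec
            fh.write(f">{gene}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name, description, tab-separated members per line)."""
    collection = GeneSetCollection()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        collection[fields[0]] = frozenset(f for f in fields[2:] if f)
    return collection


def write_gmt(collection: GeneSetCollection, path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name in sorted(collection):
            members = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def write_counts(experiment: CountsExperiment, counts_path, meta_path) -> None:
    experiment.counts.to_csv(counts_path, sep="\t")
    experiment.metadata.to_csv(meta_path)


def read_counts(counts_path, meta_path) -> CountsExperiment:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, index_col=0)
    meta["replicate"] = meta["replicate"].astype(int)
    return CountsExperiment(counts=counts, metadata=meta)


def write_panel(panel: MetabolitePanel, path, replicates_path=None) -> None:
    panel.values.to_csv(path)
    if replicates_path is not None and panel.replicate_values is not None:
        wide = panel.replicate_values.copy()
        wide.insert(0, "group", panel.replicate_groups)
        wide.to_csv(replicates_path)


def read_panel(path, cohort: str, replicates_path=None) -> MetabolitePanel:
    values = pd.read_csv(path, index_col=0)
    replicate_values = replicate_groups = None
    if replicates_path is not None:
        wide = pd.read_csv(replicates_path, index_col=0)
        replicate_groups = wide.pop("group")
        replicate_values = wide
    return MetabolitePanel(
        cohort=cohort,
        groups=tuple(values.columns),
        values=values,
        replicate_values=replicate_values,
        replicate_groups=replicate_groups,
    )


def write_study(study: SyntheticStudy, out_dir) -> dict[str, str]:
    """Write every study input to ``out_dir``; returns {logical name: path}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _p(name: str, fname: str) -> Path:
        p = out / fname
        paths[name] = str(p)
        return p

    write_fasta(study.proteome, _p("proteome", "proteome.fasta"))
    write_counts(study.counts, _p("counts", "counts.tsv"), _p("samples", "samples.csv"))
    for cohort, panel in study.panels.items():
        write_panel(
            panel,
            _p(f"panel_{cohort}", f"panel_{cohort}.csv"),
            _p(f"panel_{cohort}_replicates", f"panel_{cohort}_replicates.csv"),
        )
    write_gmt(study.gene_sets, _p("gene_sets", "gene_sets.gmt"))
    with open(_p("truth", "truth.json"), "w") as fh:
        json.dump(study.truth, fh, indent=1, sort_keys=True)
    return paths
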