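"""Readers/writers for aligned study tables and run manifests.

All on-disk tables are samples-as-rows TSV/CSV with a header row and the
sample id in the first column; a table whose first column looks like
feature ids with sample ids in the header is auto-transposed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["AlignedStudy", "read_table", "read_study", "filter_features", "write_manifest"]

log = logging.getLogger("npem")


@dataclass
class AlignedStudy:
    """Genes, taxa and outcome aligned on a common sample order."""

    genes: pd.DataFrame  # samples x genes, float
    taxa: pd.DataFrame  # samples x taxa, nonnegative int
    outcome: pd.Series  # one value per sample
    outcome_mapping: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list:
        return list(self.genes.index)


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_table(path: str | Path, sample_ids: list | None = None) -> pd.DataFrame:
    """Read a TSV/CSV feature table, index = sample ids.

    If known ``sample_ids`` appear in the header instead of the first
    column, the table is transposed.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if sample_ids is not None:
        in_index = len(set(df.index) & set(sample_ids))
        in_cols = len(set(df.columns) & set(sample_ids))
        if in_cols > in_index:
            log.info("transposing %s (sample ids found in the header)", path.name)
            df = df.T
    return df


def read_study(
    genes_path: str | Path,
    taxa_path: str | Path,
    metadata_path: str | Path,
    outcome_column: str,
) -> AlignedStudy:
    """Load and inner-join the three study tables on sample id.

    Metadata row order is preserved; dropped samples are logged.  The
    outcome must be complete; a two-level outcome is mapped to {0, 1} by
    sorted level order.
    """
    metadata_path = Path(metadata_path)
    meta = pd.read_csv(metadata_path, sep=_sep(metadata_path), index_col=0)
    if outcome_column not in meta.columns:
        raise ValueError(f"outcome column {outcome_column!r} not in metadata")
    outcome = meta[outcome_column]
    missing = outcome[outcome.isna()]
    if len(missing):
        raise ValueError(
            f"missing outcome values for samples: {list(missing.index)}"
        )
    genes = read_table(genes_path, list(meta.index))
    taxa = read_table(taxa_path, list(meta.index))
    common = [s for s in meta.index if s in genes.index and s in taxa.index]
    if not common:
        raise ValueError("no samples shared by genes, taxa and metadata")
    dropped = sorted(set(meta.index) - set(common))
    if dropped:
        log.info("dropped %d samples without full data: %s", len(dropped), dropped)
    genes = genes.loc[common].astype(float)
    taxa = taxa.loc[common]
    bad = taxa.apply(lambda c: (c.astype(float) % 1 != 0) | (c.astype(float) < 0))
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"taxa table must hold nonnegative integers; offending entry at "
            f"sample {taxa.index[r]!r}, taxon {taxa.columns[c]!r}"
        )
    taxa = taxa.astype(np.int64)
    outcome = outcome.loc[common]
    mapping: dict = {}
    if outcome.nunique() == 2:
        levels = sorted(outcome.unique(), key=str)
        mapping = {lev: i for i, lev in enumerate(levels)}
        log.info("outcome mapping: %s", mapping)
        outcome = outcome.map(mapping)
    return AlignedStudy(genes, taxa, outcome, mapping)


def filter_features(
    study: AlignedStudy,
    taxa_max_absence: float = 0.90,
    gene_lfc_min: float = 0.0,
) -> AlignedStudy:
    """Prevalence-filter taxa and (optionally) fold-change-filter genes.

    Taxa absent in more than ``taxa_max_absence`` of samples are removed.
    With ``gene_lfc_min`` > 0 and a binary outcome, genes whose absolute
    between-group log2 fold change of mean expression is below the cutoff
    are removed (off by default; meant for real-data preprocessing).
    """
    taxa = study.taxa
    absent = (taxa == 0).mean(axis=0)
    taxa = taxa.loc[:, absent <= taxa_max_absence]
    if taxa.shape[1] == 0:
        raise ValueError("taxa prevalence filter removed every taxon")
    genes = study.genes
    if gene_lfc_min > 0:
        y = study.outcome.to_numpy()
        groups = np.unique(y)
        if len(groups) != 2:
            raise ValueError("gene fold-change filter needs a two-level outcome")
        m0 = genes[y == groups[0]].mean(axis=0)
        m1 = genes[y == groups[1]].mean(axis=0)
        eps = 1e-12
        lfc = np.log2((m1.abs() + eps) / (m0.abs() + eps)).abs()
        genes = genes.loc[:, lfc >= gene_lfc_min]
        if genes.shape[1] == 0:
            raise ValueError("gene fold-change filter removed every gene")
    return AlignedStudy(genes, taxa, study.outcome, study.outcome_mapping)


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def write_manifest(out_dir: str | Path, config: dict, inputs: dict | None = None) -> Path:
    """Write a JSON run manifest (config, package version, input checksums)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "npem_version": __version__,
        "config": config,
        "inputs": {
            name: {"path": str(p), "sha256_16": _checksum(p)}
            for name, p in (inputs or {}).items()
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
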