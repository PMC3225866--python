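"""Input/output and cohort plumbing.

File formats
------------
Expression matrices are TSV/CSV with a header row of sample labels and one
gene per row (first column = gene symbol).  Interaction lists are two-column
TSV of gene symbols; gene lists hold one symbol per line.  ``#`` starts a
comment line in interaction and gene-list files.  All gene symbols are
matched case-sensitively after stripping surrounding whitespace.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Role = Literal["receptor", "transcription_factor", "cancer_mutated"]

#: Roles whose gene lists may not be empty.
_REQUIRED_ROLES = ("receptor", "transcription_factor")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample expression values for one cohort (assumed pre-normalized).

    ``data`` is a genes-by-samples DataFrame; the index holds unique gene
    symbols, the columns sample labels.  Missing values are not supported.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r} in expression matrix")
        if self.data.shape[1] < 3:
            raise ValueError(
                f"expression matrix needs >= 3 samples, got {self.data.shape[1]}"
            )
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values_for(self, gene: str) -> np.ndarray:
        return self.data.loc[gene].to_numpy(dtype=float)


@dataclass(frozen=True)
class InteractionSet:
    """Undirected protein-interaction link set; pairs stored sorted."""

    links: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.links:
            raise ValueError("interaction set is empty")
        for a, b in self.links:
            if a == b:
                raise ValueError(f"self-interaction {a!r} in interaction set")
            if a > b:
                raise ValueError("interaction pairs must be stored sorted")

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(g for link in self.links for g in link)

    def __len__(self) -> int:
        return len(self.links)


@dataclass(frozen=True)
class GeneSet:
    """A role-tagged set of gene symbols (receptors, TFs or mutated genes)."""

    role: Role
    symbols: frozenset[str]

    def __post_init__(self) -> None:
        if self.role in _REQUIRED_ROLES and not self.symbols:
            raise ValueError(f"gene list for role {self.role!r} is empty")

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols


@dataclass
class AnalysisConfig:
    """Resolved configuration for one pipeline run."""

    interactions: Path
    receptors: Path
    transcription_factors: Path
    datasets: dict[str, dict[str, Path]] = field(default_factory=dict)
    cancer_genes: Path | None = None
    seed: int = 0
    category_bounds: tuple[float, float] = (0.3, 0.5)
    hub_count: int = 50
    hub_removal_fraction: float = 0.10
    output_dir: Path = Path("results")

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be >= 0")
        if not 0.0 < self.hub_removal_fraction < 1.0:
            raise ValueError("hub removal fraction must lie in (0, 1)")
        if self.hub_count < 1:
            raise ValueError("hub count must be >= 1")


def normalize_link(a: str, b: str) -> tuple[str, str]:
    """Canonical sorted orientation of an undirected link."""
    return (a, b) if a <= b else (b, a)


def read_expression_matrix(
    path: str | Path, dialect: Literal["tsv", "csv"] = "tsv"
) -> ExpressionMatrix:
    """Read a gene x sample expression table.

    The first column carries gene symbols, the header row sample labels.
    Duplicate genes, non-numeric cells and cohorts of fewer than three
    samples are hard errors: silently aggregating probes or imputing cells
    would hide upstream mistakes.
    """
    sep = "\t" if dialect == "tsv" else ","
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    raw.index = raw.index.astype(str).str.strip()
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    if raw.shape[1] < 3:
        raise ValueError(f"{path}: needs >= 3 sample columns, found {raw.shape[1]}")
    def _cell_error(frame, kind):
        mask = frame.isna() if kind == "missing" else frame
        gene = frame.index[mask.any(axis=1)][0]
        col = frame.columns[mask.loc[gene]][0]
        raise ValueError(
            f"{path}: non-numeric or missing cell at gene {gene!r}, sample {col!r}"
        )

    if raw.isna().to_numpy().any():
        _cell_error(raw, "missing")
    try:
        data = raw.astype(float)
    except ValueError:
        bad = raw.apply(lambda c: pd.to_numeric(c, errors="coerce")).isna()
        _cell_error(bad, "flag")
    return ExpressionMatrix(data)


def read_interaction_list(path: str | Path) -> InteractionSet:
    """Read a two-column undirected interaction TSV.

    Orientation duplicates collapse to a single link; self-pairs are dropped
    with a warning.  A file yielding no links at all is a hard error.
    """
    links: set[tuple[str, str]] = set()
    n_self = n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t") if p.strip()]
            if len(parts) != 2:
                if lineno == 1:
                    continue  # tolerated header line
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            a, b = parts
            if a == b:
                n_self += 1
                continue
            link = normalize_link(a, b)
            if link in links:
                n_dup += 1
            links.add(link)
    if n_self or n_dup:
        logger.warning(
            "%s: dropped %d self-pair line(s), %d duplicate line(s)", path, n_self, n_dup
        )
    if not links:
        raise ValueError(f"{path}: no interactions found")
    return InteractionSet(frozenset(links))


def read_gene_list(path: str | Path, role: Role) -> GeneSet:
    """Read a one-symbol-per-line gene list for a given role.

    Receptor and transcription-factor lists must be non-empty; the
    cancer-mutated list is optional and may be empty (warning only).
    """
    symbols: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            symbols.add(line)
    if not symbols and role == "cancer_mutated":
        logger.warning("%s: empty cancer-mutated gene list", path)
    return GeneSet(role=role, symbols=frozenset(symbols))


def stratify_cohort(
    a: ExpressionMatrix, b: ExpressionMatrix, seed: int
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Balance two cohorts by randomly deleting samples of the larger one.

    Deletion is uniform without replacement, driven by ``seed``; the smaller
    cohort is returned unchanged and relative sample order is preserved.
    """
    if a.gene_ids != b.gene_ids:
        raise ValueError("cohorts do not share an identical gene_id ordering")
    n = min(a.n_samples, b.n_samples)
    rng = np.random.default_rng(seed)

    def _subsample(m: ExpressionMatrix) -> ExpressionMatrix:
        if m.n_samples == n:
            return m
        keep = np.sort(rng.choice(m.n_samples, size=n, replace=False))
        return ExpressionMatrix(m.data.iloc[:, keep])

    return _subsample(a), _subsample(b)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    m.data.to_csv(path, sep="\t", index_label="gene", float_format="%.12g")


def write_interaction_list(s: InteractionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(s.links):
            fh.write(f"{a}\t{b}\n")


def write_gene_list(s: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sym in sorted(s.symbols):
            fh.write(sym + "\n")


def write_feature_report(
    features: pd.DataFrame,
    motifs: pd.DataFrame,
    comparison: pd.DataFrame,
    out_dir: str | Path,
    extra: dict | None = None,
) -> dict[str, Path]:
    """Write the three result tables plus a machine-readable JSON twin.

    Values survive a write/read round trip to 12 significant digits.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": out / "features.tsv",
        "motifs": out / "motifs.tsv",
        "comparison": out / "comparison.tsv",
        "report": out / "report.json",
    }
    features.to_csv(paths["features"], sep="\t", index=False, float_format="%.12g")
    motifs.to_csv(paths["motifs"], sep="\t", index=False, float_format="%.12g")
    comparison.to_csv(paths["comparison"], sep="\t", index=False, float_format="%.12g")
    report = {
        "features": features.to_dict(orient="records"),
        "motifs": motifs.to_dict(orient="records"),
        "comparison": comparison.to_dict(orient="records"),
    }
    if extra:
        report.update(extra)
    with open(paths["report"], "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return paths


def read_feature_report(out_dir: str | Path) -> dict:
    with open(Path(out_dir) / "report.json") as fh:
        return json.load(fh)


def load_published_cohort_features() -> pd.DataFrame:
    """Published per-dataset feature values for the twenty tumor/normal pairs.

    Tidy table with columns ``dataset, feature, normal, tumor`` transcribed
    from the published cross-tumor compendium this package re-implements the
    analysis of.  These printed values are the input of the cross-dataset
    paired-comparison stage.
    """
    ref = resources.files("corsignet.data") / "published_cohort_features.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")
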