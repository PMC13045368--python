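"""Condition embeddings injected into every denoiser block.

Three condition channels steer the denoiser: a categorical domain label
``c`` drawn from a finite registered set, a genomic profile ``{(g_i, m_i)}``
of boolean mutation bits over a registered gene set, and a transcriptomic
profile ``{(g_i, t_i)}`` of quantile-normalized expression values over the
same registry.  Each gene carries a wild-type embedding ``e_g`` and a mutant
embedding ``e~_g``; the genomic condition is the sum over genes of an MLP
applied to whichever of the two the mutation bit selects.  The
transcriptomic condition is the sum over genes of an element-wise product of
a gene-identity MLP and an expression MLP that receives the gene embedding
concatenated with the scalar ``t_i``, keeping identity and quantity
separable.  The combined vector ``e_cat + e_genomic + e_transcriptomic`` is
what the U-Net adds to every residual block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .nn import MLP, Parameter, Tensor, concat

__all__ = ["CategoricalCondition", "GenomicProfile", "TranscriptomicProfile",
           "ConditionBundle", "EmbeddingTables", "embed_categorical",
           "embed_genomic", "embed_transcriptomic", "combine_conditions",
           "embed_bundles", "quantile_normalize", "read_genomic_tsv",
           "read_transcriptomic_tsv", "read_genomic_matrix",
           "read_transcriptomic_matrix"]


@dataclass(frozen=True)
class CategoricalCondition:
    label: str


@dataclass(frozen=True)
class GenomicProfile:
    """Mutation status per registered gene (True = non-synonymous mutation)."""
    entries: dict[str, bool]


@dataclass(frozen=True)
class TranscriptomicProfile:
    """Quantile-normalized expression value per registered gene."""
    entries: dict[str, float]


@dataclass(frozen=True)
class ConditionBundle:
    categorical: CategoricalCondition
    genomic: GenomicProfile | None = None
    transcriptomic: TranscriptomicProfile | None = None

    @staticmethod
    def make(label: str, genomic: dict[str, bool] | None = None,
             transcriptomic: dict[str, float] | None = None) -> "ConditionBundle":
        return ConditionBundle(
            CategoricalCondition(label),
            GenomicProfile(dict(genomic)) if genomic is not None else None,
            TranscriptomicProfile(dict(transcriptomic)) if transcriptomic is not None else None,
        )


class EmbeddingTables:
    """Learned tables and MLP heads for all three condition channels.

    Parameters
    ----------
    labels : list of registered categorical labels (order fixes table rows)
    genes : registered gene set for genomic (mutation) profiles
    dim : embedding width; must match the denoiser's block-injection width
    rng : generator used for initialization
    expression_genes : registered gene set for transcriptomic profiles;
        defaults to `genes` but may differ (mutation and expression panels
        are typically different sizes)
    """

    def __init__(self, labels: list[str], genes: list[str], dim: int,
                 rng: np.random.Generator,
                 expression_genes: list[str] | None = None):
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate categorical labels")
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene names")
        expression_genes = list(genes) if expression_genes is None \
            else list(expression_genes)
        if len(set(expression_genes)) != len(expression_genes):
            raise ValueError("duplicate expression gene names")
        self.labels = list(labels)
        self.genes = list(genes)
        self.expression_genes = expression_genes
        self.dim = dim
        self._label_index = {c: i for i, c in enumerate(self.labels)}
        n_g = max(len(genes), 1)
        n_e = max(len(expression_genes), 1)
        # unit-scale rows, the class-embedding convention of conditional
        # diffusion models: the condition signal must be visible against the
        # O(1) timestep embedding from the first optimizer step
        scale = 1.0
        f32 = np.float32
        self.categorical_table = Parameter(
            (rng.standard_normal((max(len(labels), 1), dim)) * scale).astype(f32))
        self.wt_table = Parameter((rng.standard_normal((n_g, dim)) * scale).astype(f32))
        self.mut_table = Parameter((rng.standard_normal((n_g, dim)) * scale).astype(f32))
        self.txn_gene_table = Parameter(
            (rng.standard_normal((n_e, dim)) * scale).astype(f32))
        self.mlp_genomic = MLP(dim, dim, dim, rng)
        self.mlp_transcriptomic = MLP(dim, dim, dim, rng)
        self.mlp_exp = MLP(dim + 1, dim, dim, rng)

    def params(self) -> dict[str, Parameter]:
        out = {"categorical_table": self.categorical_table,
               "wt_table": self.wt_table, "mut_table": self.mut_table,
               "txn_gene_table": self.txn_gene_table}
        for name in ("mlp_genomic", "mlp_transcriptomic", "mlp_exp"):
            for k, v in getattr(self, name).params().items():
                out[f"{name}.{k}"] = v
        return out

    def _check_profile(self, entries: dict, registry: list[str], what: str) -> None:
        keys = set(entries)
        registered = set(registry)
        missing = sorted(registered - keys)
        extra = sorted(keys - registered)
        if missing or extra:
            raise KeyError(f"{what} profile mismatch with gene registry: "
                           f"missing={missing}, extra={extra}")


def embed_categorical(c: CategoricalCondition, tables: EmbeddingTables) -> Tensor:
    """Row lookup in the categorical table."""
    if c.label not in tables._label_index:
        raise KeyError(f"unregistered categorical label {c.label!r} "
                       f"(registered: {tables.labels})")
    i = tables._label_index[c.label]
    sel = np.zeros((1, tables.categorical_table.data.shape[0]), dtype=np.float32)
    sel[0, i] = 1.0
    return (Tensor(sel) @ tables.categorical_table).reshape(tables.dim)


def embed_genomic(profile: GenomicProfile, tables: EmbeddingTables) -> Tensor:
    """sum_i MLP_genomic(e_g if WT else e~_g), vectorized over the registry."""
    tables._check_profile(profile.entries, tables.genes, "genomic")
    n = len(tables.genes)
    if n == 0:
        return Tensor(np.zeros(tables.dim, dtype=np.float32))
    mask = np.array([[1.0 if profile.entries[g] else 0.0] for g in tables.genes],
                    dtype=np.float32)
    rows = tables.mut_table * Tensor(mask) + tables.wt_table * Tensor(1.0 - mask)
    return tables.mlp_genomic(rows).sum(axis=0)


def embed_transcriptomic(profile: TranscriptomicProfile,
                         tables: EmbeddingTables) -> Tensor:
    """sum_i MLP_txn(e_g) * MLP_exp([e_g, t_i]) with element-wise product."""
    tables._check_profile(profile.entries, tables.expression_genes, "transcriptomic")
    n = len(tables.expression_genes)
    if n == 0:
        return Tensor(np.zeros(tables.dim, dtype=np.float32))
    t_vals = np.array([[profile.entries[g]] for g in tables.expression_genes],
                      dtype=np.float64)
    if not np.all(np.isfinite(t_vals)):
        bad = [g for g in tables.expression_genes
               if not np.isfinite(profile.entries[g])]
        raise ValueError(f"non-finite expression values for genes {bad}")
    gene_part = tables.mlp_transcriptomic(tables.txn_gene_table)
    exp_in = concat([tables.txn_gene_table, Tensor(t_vals.astype(np.float32))], axis=1)
    exp_part = tables.mlp_exp(exp_in)
    return (gene_part * exp_part).sum(axis=0)


def combine_conditions(bundle: ConditionBundle, tables: EmbeddingTables) -> Tensor:
    """e_cat + e_genomic + e_transcriptomic; absent omics contribute zero."""
    out = embed_categorical(bundle.categorical, tables)
    if bundle.genomic is not None:
        out = out + embed_genomic(bundle.genomic, tables)
    if bundle.transcriptomic is not None:
        out = out + embed_transcriptomic(bundle.transcriptomic, tables)
    return out


def embed_bundles(bundles: list[ConditionBundle], tables: EmbeddingTables) -> Tensor:
    """Stack combined condition vectors into a (batch, dim) tensor."""
    rows = [combine_conditions(b, tables).reshape(1, tables.dim) for b in bundles]
    return rows[0] if len(rows) == 1 else concat(rows, axis=0)


# --------------------------------------------------------------------- tabular
def quantile_normalize(raw: pd.DataFrame) -> pd.DataFrame:
    """Rank-based per-gene normalization to (0, 1) across samples.

    Each gene (column) is replaced by ``rank / (n_samples + 1)`` with average
    ranks for ties, so every gene shares the same marginal grid up to ties.
    An all-identical column maps to 0.5 everywhere.
    """
    if raw.shape[0] < 1 or raw.shape[1] < 1:
        raise ValueError("need at least one sample and one gene")
    values = raw.to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise ValueError("raw expression contains non-finite values")
    ranks = rankdata(values, axis=0, method="average")
    return pd.DataFrame(ranks / (values.shape[0] + 1.0),
                        index=raw.index, columns=raw.columns)


def read_genomic_tsv(path) -> GenomicProfile:
    """Read a two-column TSV (gene, status in {0,1}) into a GenomicProfile."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    if not {"gene", "status"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'gene' and 'status'")
    return GenomicProfile({g: bool(int(s)) for g, s in zip(df["gene"], df["status"])})


def read_transcriptomic_tsv(path) -> TranscriptomicProfile:
    """Read a two-column TSV (gene, value) into a TranscriptomicProfile."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    if not {"gene", "value"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'gene' and 'value'")
    return TranscriptomicProfile({g: float(v) for g, v in zip(df["gene"], df["value"])})


def _read_wide(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns:
        raise ValueError(f"{path}: wide profile matrices need a 'sample' column")
    return df.set_index("sample")


def read_genomic_matrix(path) -> dict[str, GenomicProfile]:
    """Wide TSV (sample column + one 0/1 column per gene) -> profiles by sample."""
    df = _read_wide(path)
    return {s: GenomicProfile({g: bool(int(v)) for g, v in row.items()})
            for s, row in df.iterrows()}


def read_transcriptomic_matrix(path) -> dict[str, TranscriptomicProfile]:
    """Wide TSV (sample column + one float column per gene) -> profiles by sample."""
    df = _read_wide(path)
    return {s: TranscriptomicProfile({g: float(v) for g, v in row.items()})
            for s, row in df.iterrows()}
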