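"""Relative gene expression by the multi-reference ΔΔCt method.

For a target gene t and reference genes g₁…g_K (here typically ACTB, GAPDH,
RPLP0 and POLR2F, so K = 4 and the exponent carries a ¼ coefficient):

    ΔCt_g = mean Ct_{g,control} − mean Ct_{g,sample}
    R     = 2^( ΔCt_target − (1/K) · Σ_k ΔCt_{g_k} )

R > 1 means the target is up-regulated in the sample condition relative to
the reference-gene panel; the formula assumes amplification efficiency 2
for every gene.  Significance is assessed with a permutation test that
relabels replicate condition assignments jointly across genes (preserving
replicate linkage), the randomization analogue of the bootstrap test used
by dedicated relative-expression software.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InsufficientReplicatesError, MissingConditionError

__all__ = [
    "DEFAULT_REFERENCE_GENES",
    "CtTable",
    "ExpressionResult",
    "delta_ct",
    "relative_expression",
    "permutation_test",
]

DEFAULT_REFERENCE_GENES = ("ACTB", "GAPDH", "RPLP0", "POLR2F")

_CONDITIONS = ("control", "sample")


@dataclass(frozen=True)
class ExpressionResult:
    gene: str
    R: float                 # relative expression, fold
    delta_ct_target: float   # cycles
    p_value: float | None = None


class CtTable:
    """Ct values per gene × condition × replicate.

    Wraps a tidy DataFrame with columns ``gene``, ``role``
    (``target`` | ``reference``), ``condition`` (``control`` | ``sample``),
    ``replicate`` and ``Ct`` (cycles, > 0).
    """

    REQUIRED = ("gene", "role", "condition", "replicate", "Ct")

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise ValueError(f"Ct table missing columns {missing}")
        bad_cond = set(data["condition"]) - set(_CONDITIONS)
        if bad_cond:
            raise ValueError(f"unknown conditions {sorted(bad_cond)}")
        if (data["Ct"] <= 0).any():
            raise ValueError("all Ct values must be > 0")
        for gene, sub in data.groupby("gene"):
            conds = set(sub["condition"])
            if conds != set(_CONDITIONS):
                raise MissingConditionError(
                    f"gene {gene} missing condition(s) "
                    f"{sorted(set(_CONDITIONS) - conds)}")
        self.data = data.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CtTable":
        return cls(pd.read_csv(path))

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    def reference_genes(self) -> list[str]:
        return sorted(self.data.loc[self.data["role"] == "reference",
                                    "gene"].unique())

    def target_genes(self) -> list[str]:
        return sorted(self.data.loc[self.data["role"] == "target",
                                    "gene"].unique())

    def ct(self, gene: str, condition: str) -> np.ndarray:
        sub = self.data[(self.data["gene"] == gene)
                        & (self.data["condition"] == condition)]
        if len(sub) == 0:
            raise MissingConditionError(
                f"gene {gene} has no Ct values for condition {condition}")
        return sub["Ct"].to_numpy(float)

    def wide(self) -> pd.DataFrame:
        """Genes × (condition, replicate) matrix; requires full linkage."""
        w = self.data.pivot_table(index="gene",
                                  columns=["condition", "replicate"],
                                  values="Ct")
        if w.isna().any().any():
            raise ValueError("incomplete replicate linkage: every replicate "
                             "must carry a Ct for every gene")
        return w


def delta_ct(table: CtTable, gene: str) -> float:
    """ΔCt = mean Ct over control replicates − mean over sample replicates."""
    return float(table.ct(gene, "control").mean()
                 - table.ct(gene, "sample").mean())


def relative_expression(table: CtTable, target_gene: str,
                        reference_genes=DEFAULT_REFERENCE_GENES,
                        ) -> ExpressionResult:
    """R = 2^(ΔCt_target − mean reference ΔCt)."""
    reference_genes = list(reference_genes)
    if len(reference_genes) < 1:
        raise ValueError("need at least one reference gene")
    if target_gene in reference_genes:
        raise ValueError(
            f"target gene {target_gene} cannot be one of the references")
    dct_t = delta_ct(table, target_gene)
    dct_refs = [delta_ct(table, g) for g in reference_genes]
    r = 2.0 ** (dct_t - float(np.mean(dct_refs)))
    return ExpressionResult(gene=target_gene, R=r, delta_ct_target=dct_t)


def _log2_r(wide: pd.DataFrame, control_cols, sample_cols, target: str,
            refs: list[str]) -> float:
    ct_c = wide[control_cols]
    ct_s = wide[sample_cols]
    dct = ct_c.mean(axis=1) - ct_s.mean(axis=1)
    return float(dct[target] - dct[refs].mean())


def permutation_test(table: CtTable, target_gene: str,
                     reference_genes=DEFAULT_REFERENCE_GENES,
                     n_perm: int = 10_000, seed: int | None = None,
                     ) -> float:
    """Two-sided permutation p-value for R ≠ 1.

    The null distribution is built by relabelling replicate condition
    assignments — whole replicates (all genes jointly) are reassigned to
    control/sample, preserving group sizes and the replicate linkage across
    genes.  p = (1 + #{|log2 R_perm| ≥ |log2 R_obs|}) / (n_perm + 1).
    """
    reference_genes = list(reference_genes)
    if target_gene in reference_genes:
        raise ValueError(
            f"target gene {target_gene} cannot be one of the references")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    wide = table.wide()
    cols = list(wide.columns)
    control_cols = [c for c in cols if c[0] == "control"]
    sample_cols = [c for c in cols if c[0] == "sample"]
    if len(control_cols) < 2 or len(sample_cols) < 2:
        raise InsufficientReplicatesError(
            "permutation test needs >= 2 replicates per condition "
            f"(got {len(control_cols)} control, {len(sample_cols)} sample)")

    obs = abs(_log2_r(wide, control_cols, sample_cols, target_gene,
                      reference_genes))
    rng = np.random.default_rng(seed)
    n_c = len(control_cols)
    arr = wide.to_numpy(float)
    target_i = list(wide.index).index(target_gene)
    ref_i = [list(wide.index).index(g) for g in reference_genes]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(cols))
        c_idx, s_idx = perm[:n_c], perm[n_c:]
        dct = arr[:, c_idx].mean(axis=1) - arr[:, s_idx].mean(axis=1)
        stat = abs(dct[target_i] - dct[ref_i].mean())
        if stat >= obs - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)
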