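"""Core in-memory containers for two-class expression data and results.

The universal input is a genes x samples matrix of (log-scale) expression
values with a control/treatment label per column.  Statistics follow the
two-class unpaired convention in which the per-gene numerator is
``mean(control) - mean(treatment)``: a POSITIVE statistic means higher
expression in the control group, a NEGATIVE statistic means higher expression
in the treatment group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTROL = "control"
TREATMENT = "treatment"

#: statistic method tags understood throughout the package
METHODS = ("sam", "msam1", "msam2", "sam_tbor", "sam_wilcoxon")


class DegenerateDataError(ValueError):
    """Raised when an input is too degenerate for the requested statistic
    (e.g. every scatter zero, or a fully constant dataset)."""


@dataclass(frozen=True)
class TwoGroupExpression:
    """A validated genes x samples expression matrix with group labels.

    Parameters
    ----------
    values
        2-D float array, shape ``(n_genes, n1 + n2)``; all entries finite.
    gene_ids
        Unique identifier per row.
    group
        Per-column label, each either ``"control"`` or ``"treatment"``.
        At least two replicates are required per group because every scatter
        estimate needs within-group spread.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        gene_ids = np.asarray(self.gene_ids)
        group = np.asarray(self.group)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "group", group)

        if values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples matrix")
        if gene_ids.shape != (values.shape[0],):
            raise ValueError("gene_ids length must match the number of rows")
        if group.shape != (values.shape[1],):
            raise ValueError("group length must match the number of columns")
        if not np.isfinite(values).all():
            raise ValueError("expression values must all be finite (no NaN/inf)")
        bad = set(np.unique(group)) - {CONTROL, TREATMENT}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)!r}")
        if len(np.unique(gene_ids)) != len(gene_ids):
            raise ValueError("gene_ids must be unique")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError(
                "each group needs at least 2 replicates "
                f"(got n1={self.n1}, n2={self.n2})"
            )

    # -- convenience views -------------------------------------------------
    @property
    def control_mask(self) -> np.ndarray:
        return self.group == CONTROL

    @property
    def treatment_mask(self) -> np.ndarray:
        return self.group == TREATMENT

    @property
    def control_values(self) -> np.ndarray:
        return self.values[:, self.control_mask]

    @property
    def treatment_values(self) -> np.ndarray:
        return self.values[:, self.treatment_mask]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n1(self) -> int:
        return int(self.control_mask.sum())

    @property
    def n2(self) -> int:
        return int(self.treatment_mask.sum())


@dataclass(frozen=True)
class StatisticResult:
    """Per-gene test statistics for one method.

    For the mean-difference methods (``sam``, ``msam1``, ``msam2``,
    ``sam_tbor``) the elementwise identity
    ``statistic = numerator / (scatter + s0)`` holds; the rank-based
    ``sam_wilcoxon`` comparator carries NaN ``scatter``/``s0``.
    """

    gene_ids: np.ndarray
    numerator: np.ndarray
    scatter: np.ndarray
    s0: float
    statistic: np.ndarray
    method: str

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method tag {self.method!r}")

    def to_frame(self) -> pd.DataFrame:
        """Per-gene table: gene_id, numerator, scatter, s0, statistic, method."""
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "numerator": self.numerator,
                "scatter": self.scatter,
                "s0": self.s0,
                "statistic": self.statistic,
                "method": self.method,
            }
        )


@dataclass(frozen=True)
class GaussianWeightSpec:
    """Calibrated bandwidth of the Gaussian (MSAM1) weight.

    ``m`` is the maximal absolute deviation from the per-gene, per-group
    median over the WHOLE dataset; ``sigma`` solves
    ``m = F^{-1}(1 - p; 0, sigma)``, i.e. ``sigma = m / z_{1-p}`` with the
    one-sided standard-normal quantile ``z_{1-p}``.
    """

    p: float
    m: float
    sigma: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError("tail probability p must lie in (0, 1)")
        if self.m <= 0 or self.sigma <= 0:
            raise ValueError("m and sigma must be positive")


@dataclass(frozen=True)
class TruthLabels:
    """Ground-truth differential-expression labels of a simulated dataset.

    ``up_genes`` are truly induced in the TREATMENT group (so under the
    ``mean(control) - mean(treatment)`` numerator their statistics are
    expected to be negative); ``down_genes`` are truly suppressed in
    treatment.  ``outlier_columns`` lists the treatment column indices that
    carry the contamination term (empty in low-noise scenarios).
    """

    up_genes: np.ndarray
    down_genes: np.ndarray
    outlier_columns: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=int)
    )

    def __post_init__(self) -> None:
        up = np.asarray(self.up_genes, dtype=int)
        down = np.asarray(self.down_genes, dtype=int)
        object.__setattr__(self, "up_genes", up)
        object.__setattr__(self, "down_genes", down)
        object.__setattr__(
            self, "outlier_columns", np.asarray(self.outlier_columns, dtype=int)
        )
        if np.intersect1d(up, down).size:
            raise ValueError("a gene cannot be both up- and down-regulated")

    @property
    def true_genes(self) -> np.ndarray:
        return np.union1d(self.up_genes, self.down_genes)

    @property
    def n_true(self) -> int:
        return self.up_genes.size + self.down_genes.size


@dataclass(frozen=True)
class SignificanceCall:
    """Outcome of a delta-band significance call.

    ``up_genes`` / ``down_genes`` are row indices into the original gene
    order ("up" = positive side of the statistic).  ``d_up`` is the smallest
    statistic among significantly positive genes and ``d_down`` the largest
    among significantly negative genes (+/- inf when the side is empty).
    FDR estimates are present only after permutation-based estimation;
    reported values are capped at 1, raw ratios are kept alongside.
    """

    delta: float
    d_up: float
    d_down: float
    up_genes: np.ndarray
    down_genes: np.ndarray
    fdr_median: float | None = None
    fdr_mean: float | None = None
    fdr_median_raw: float | None = None
    fdr_mean_raw: float | None = None

    @property
    def n_called(self) -> int:
        return self.up_genes.size + self.down_genes.size

    @property
    def called_genes(self) -> np.ndarray:
        return np.concatenate([self.up_genes, self.down_genes])
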