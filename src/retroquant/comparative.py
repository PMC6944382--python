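"""Between-condition comparisons of repeat expression.

Fold changes between two conditions are summarized as the median of all
pairwise replicate log2 ratios: for replicates a_1..a_m of condition A and
b_1..b_n of condition B, the per-unit statistic is

    median over (i, j) of log2((rpm_bj + pc) / (rpm_ai + pc))

with a small pseudocount pc (default 0.1 RPM) because zero counts are
common for repeat units.  The median over all m*n pairs is robust to a
single outlying replicate and antisymmetric under swapping conditions.

Also provided: relative-to-control RPM ratios for aggregated tables,
sample-sample correlation matrices on RPKM vectors, and the row-scaled
relative-expression matrix used for stage heatmaps (each unit's row is
divided by its maximum across stages; all-zero rows stay zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .repeat_quant import AggregateTable, CountTable


@dataclass
class FoldChangeTable:
    """Median-of-pairwise-log2FC per unit between two conditions."""

    condition_a: str
    condition_b: str
    pseudocount: float
    table: pd.DataFrame  # index unit; columns median_log2fc, n_pairs
    pair_values: dict[str, list[float]]

    def to_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with Path(path).open("w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            df = self.table.copy()
            df.insert(0, "unit", df.index)
            df.to_csv(fh, sep="\t", index=False)


@dataclass
class CorrelationMatrix:
    method: str
    matrix: pd.DataFrame  # symmetric, unit diagonal, sample x sample

    def to_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with Path(path).open("w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.matrix.to_csv(fh, sep="\t")


def _rpm_vectors(tables: Sequence[CountTable], units: Sequence[str]) -> np.ndarray:
    mat = np.zeros((len(units), len(tables)))
    for j, t in enumerate(tables):
        rpm = t.counts["rpm"].reindex(units, fill_value=0.0)
        if rpm.isna().any():
            raise ValueError(f"sample {t.sample_id}: RPM not computed")
        mat[:, j] = rpm.to_numpy()
    return mat


def median_pairwise_log2fc(
    tables_a: Sequence[CountTable],
    tables_b: Sequence[CountTable],
    pseudocount: float = 0.1,
    condition_a: str = "A",
    condition_b: str = "B",
) -> FoldChangeTable:
    """Median over all (replicate_a, replicate_b) pairs of log2 RPM ratios.

    The median uses the mean of the two middle values for an even number
    of pairs.  Units absent from a replicate enter with RPM 0.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if not tables_a or not tables_b:
        raise ValueError("both conditions need >=1 replicate")
    levels = {t.unit_level for t in (*tables_a, *tables_b)}
    if len(levels) != 1:
        raise ValueError(f"conditions mix unit levels: {sorted(levels)}")
    units = sorted(
        set().union(*(t.counts.index for t in (*tables_a, *tables_b)))
    )
    a = _rpm_vectors(tables_a, units) + pseudocount
    b = _rpm_vectors(tables_b, units) + pseudocount
    # all m*n pairwise log-ratios per unit, vectorized over units
    ratios = np.log2(b[:, None, :] / a[:, :, None])  # unit x rep_a x rep_b
    flat = ratios.reshape(len(units), -1)
    medians = np.median(flat, axis=1)
    table = pd.DataFrame(
        {"median_log2fc": medians, "n_pairs": flat.shape[1]},
        index=pd.Index(units, name="unit"),
    )
    pair_values = {u: flat[i].tolist() for i, u in enumerate(units)}
    return FoldChangeTable(
        condition_a=condition_a,
        condition_b=condition_b,
        pseudocount=pseudocount,
        table=table,
        pair_values=pair_values,
    )


def relative_to_control(
    mutant: AggregateTable, control: AggregateTable, pseudocount: float = 0.1
) -> pd.Series:
    """Per-unit ratio (mean RPM mutant + pc) / (mean RPM control + pc)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    units = sorted(set(mutant.mean_rpm.index) | set(control.mean_rpm.index))
    m = mutant.mean_rpm.reindex(units, fill_value=0.0) + pseudocount
    c = control.mean_rpm.reindex(units, fill_value=0.0) + pseudocount
    ratio = m / c
    ratio.name = "ratio_vs_control"
    ratio.index.name = "unit"
    return ratio


def correlation_matrix(
    vectors: pd.DataFrame | Mapping[str, Sequence[float]],
    method: str = "pearson",
    log_transform: bool = False,
    pseudocount: float = 0.1,
) -> CorrelationMatrix:
    """Sample-sample correlation of per-unit RPKM vectors.

    ``vectors`` is units x samples (columns are samples, aligned on an
    identical unit ordering).  With ``log_transform`` a uniform
    log2(x + pseudocount) is applied first.
    """
    df = pd.DataFrame(vectors)
    if df.shape[1] < 2:
        raise ValueError("need >=2 samples")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    if log_transform:
        if pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        df = np.log2(df + pseudocount)
    for col in df.columns:
        if np.isclose(df[col].std(ddof=0), 0.0):
            raise ValueError(f"sample {col}: zero-variance vector")
    return CorrelationMatrix(method=method, matrix=df.corr(method=method))


def relative_expression_matrix(
    stage_tables: Sequence[AggregateTable],
    stage_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Unit x stage matrix with each row scaled to a maximum of 1.

    All-zero rows are left at zero (no division).  Used for heatmaps of
    repeat expression across developmental stages.
    """
    if len(stage_tables) < 2:
        raise ValueError("need >=2 stages")
    if stage_names is None:
        stage_names = [f"stage{i}" for i in range(len(stage_tables))]
    units = sorted(set().union(*(t.mean_rpm.index for t in stage_tables)))
    mat = pd.DataFrame(
        {
            name: t.mean_rpm.reindex(units, fill_value=0.0)
            for name, t in zip(stage_names, stage_tables)
        },
        index=pd.Index(units, name="unit"),
    )
    row_max = mat.max(axis=1)
    nonzero = row_max > 0
    mat.loc[nonzero] = mat.loc[nonzero].div(row_max[nonzero], axis=0)
    return mat
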