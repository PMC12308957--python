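"""Expression-matrix I/O, gene filtering, and the pair-screening driver."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import FitConfig, fit_pair, predict_curves
from .inference import (PairScreenResult, aud, bh_adjust, delta_rho_bar,
                        max_abs_diff, shared_grid, test_group_difference_rho)

logger = logging.getLogger(__name__)


@dataclass
class ExpressionDataset:
    """A cells x genes matrix with per-cell pseudotime and group labels."""

    matrix: pd.DataFrame              # index = cell ids, columns = gene names
    pseudotime: pd.Series
    group: pd.Series

    def __post_init__(self) -> None:
        m = self.matrix
        if (m.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if m.columns.duplicated().any():
            dup = m.columns[m.columns.duplicated()][0]
            raise ValueError(f"duplicate gene name {dup!r}")
        missing = m.index.difference(self.pseudotime.index)
        if len(missing):
            raise ValueError(f"metadata missing for cell {missing[0]!r}")
        self.pseudotime = self.pseudotime.loc[m.index].astype(float)
        self.group = self.group.loc[m.index]
        if not np.isfinite(self.pseudotime.values).all():
            raise ValueError("pseudotime must be finite")

    @property
    def genes(self):
        return list(self.matrix.columns)

    @property
    def cells(self):
        return list(self.matrix.index)

    def group_codes(self) -> np.ndarray:
        """Group labels coded 1..G (reference = first label in sorted order,
        with 'wild-type'-like labels preferred as reference when present)."""
        labels = sorted(self.group.unique(), key=_group_sort_key)
        mapping = {lab: i + 1 for i, lab in enumerate(labels)}
        return self.group.map(mapping).to_numpy(dtype=int)

    def expression(self, gene: str) -> np.ndarray:
        return self.matrix[gene].to_numpy(dtype=float)


def _group_sort_key(label):
    s = str(label).lower()
    if s in ("wt", "wild-type", "wildtype", "control", "1"):
        return (0, s)
    return (1, s)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep=None, engine="python")
    required = {"cell_id", "pseudotime", "group"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata needs columns {sorted(required)}")
    return meta.set_index("cell_id")


def read_expression(path, format: str | None = None,
                    metadata=None) -> ExpressionDataset:
    """Read a cells x genes expression matrix plus cell metadata.

    ``format`` is one of ``csv``, ``tsv`` or ``mtx_triplet`` (Matrix Market
    with ``<stem>.genes.txt`` / ``<stem>.cells.txt`` name sidecars); when
    omitted it is inferred from the file suffix.  ``metadata`` is a path to
    a table with columns ``cell_id, pseudotime, group`` or an equivalent
    DataFrame indexed by cell id.
    """
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".mtx": "mtx_triplet"}.get(
            path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer format from {path.name!r}")
    if format in ("csv", "tsv"):
        mat = pd.read_csv(path, sep="," if format == "csv" else "\t",
                          index_col=0, float_precision="round_trip")
    elif format == "mtx_triplet":
        from scipy.io import mmread
        m = np.asarray(mmread(str(path)).todense() if hasattr(
            mmread(str(path)), "todense") else mmread(str(path)), dtype=float)
        stem = path.with_suffix("")
        genes = Path(f"{stem}.genes.txt").read_text().split()
        cells = Path(f"{stem}.cells.txt").read_text().split()
        if m.shape != (len(cells), len(genes)):
            raise ValueError(
                f"matrix shape {m.shape} does not match sidecars "
                f"({len(cells)} cells, {len(genes)} genes)")
        mat = pd.DataFrame(m, index=cells, columns=genes)
    else:
        raise ValueError(f"unknown format {format!r}")
    if metadata is None:
        raise ValueError("metadata (cell_id, pseudotime, group) is required")
    meta = metadata if isinstance(metadata, pd.DataFrame) else read_metadata(metadata)
    return ExpressionDataset(matrix=mat, pseudotime=meta["pseudotime"],
                             group=meta["group"])


def write_expression(dataset: ExpressionDataset, path, format: str = "csv") -> None:
    path = Path(path)
    sep = "," if format == "csv" else "\t"
    dataset.matrix.to_csv(path, sep=sep)


def filter_genes(dataset: ExpressionDataset,
                 max_zero_fraction: float = 0.8) -> ExpressionDataset:
    """Drop genes whose zero fraction strictly exceeds the threshold."""
    if not 0 < max_zero_fraction <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    zf = (dataset.matrix.values == 0).mean(axis=0)
    keep = zf <= max_zero_fraction
    removed = [g for g, k in zip(dataset.genes, keep) if not k]
    if removed:
        logger.info("removed %d genes with > %.0f%% zeros: %s",
                    len(removed), 100 * max_zero_fraction, ", ".join(removed))
    if not keep.any():
        raise ValueError("all genes removed by the zero-fraction filter")
    return ExpressionDataset(matrix=dataset.matrix.loc[:, keep],
                             pseudotime=dataset.pseudotime,
                             group=dataset.group)


@dataclass
class ScreenPlan:
    """Which pairs to screen, plus screening options."""

    pairs: list                       # list of (gene1, gene2)
    n_time: int = 100
    grid_mode: str = "overlap"

    @classmethod
    def all_pairs(cls, genes, **kw) -> "ScreenPlan":
        """Unordered pairs (i < j): C(len(genes), 2) combinations."""
        return cls(pairs=list(itertools.combinations(genes, 2)), **kw)

    def validate(self, dataset: ExpressionDataset) -> None:
        known = set(dataset.genes)
        for g1, g2 in self.pairs:
            if g1 not in known or g2 not in known:
                missing = g1 if g1 not in known else g2
                raise ValueError(f"gene {missing!r} not in the dataset")


def screen_pair(dataset: ExpressionDataset, gene1: str, gene2: str,
                plan: ScreenPlan, config: FitConfig):
    """Fit one pair and compute its test and curve-difference metrics."""
    y1 = dataset.expression(gene1)
    y2 = dataset.expression(gene2)
    z = dataset.pseudotime.to_numpy()
    group = dataset.group_codes()
    try:
        fit = fit_pair(y1, y2, z, group, config=config)
        test = test_group_difference_rho(y1, y2, z, group, config=config,
                                         full_fit=fit)
        grid = shared_grid(z, group, n_time=plan.n_time, mode=plan.grid_mode)
        rho_wt = predict_curves(fit, grid, group=1, parameters=["rho"])["rho"]["value"]
        rho_mut = predict_curves(fit, grid, group=2, parameters=["rho"])["rho"]["value"]
        return PairScreenResult(
            gene1=gene1, gene2=gene2, p_value=test.p_value, p_adjusted=np.nan,
            delta_rho_bar=delta_rho_bar(rho_wt, rho_mut),
            max_abs_diff=max_abs_diff(rho_wt, rho_mut),
            aud=aud(rho_wt, rho_mut, grid),
            converged=fit.converged and np.isfinite(test.p_value))
    except Exception as err:            # a failed pair must not abort the screen
        logger.warning("pair (%s, %s) failed: %s", gene1, gene2, err)
        return PairScreenResult(gene1=gene1, gene2=gene2, p_value=np.nan,
                                p_adjusted=np.nan, delta_rho_bar=np.nan,
                                max_abs_diff=np.nan, aud=np.nan, converged=False)


def run_screen(dataset: ExpressionDataset, plan: ScreenPlan,
               config: FitConfig | None = None, out=None) -> pd.DataFrame:
    """Screen every planned gene pair for group-differential co-expression.

    Each pair is fitted independently (processing order does not influence
    the result); Benjamini-Hochberg adjustment is applied across all
    attempted pairs at the end.  The returned table is sorted by adjusted
    p-value, then gene names; ``out`` optionally writes it as TSV.
    """
    config = config or FitConfig()
    plan.validate(dataset)
    results = [screen_pair(dataset, g1, g2, plan, config)
               for g1, g2 in plan.pairs]
    df = pd.DataFrame([r.__dict__ for r in results])
    df["p_adjusted"] = bh_adjust(df["p_value"].to_numpy())
    df = df.sort_values(["p_adjusted", "gene1", "gene2"],
                        na_position="last").reset_index(drop=True)
    if out is not None:
        df.to_csv(out, sep="\t", index=False)
    return df
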