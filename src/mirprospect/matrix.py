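"""Expression matrix container with explicit processing-state tracking.

Microarray preprocessing is a short chain of transformations — background
subtraction, replicate collapse, quantile normalization, log2 — and silent
reordering of those steps is a classic source of irreproducible results.
:class:`ExpressionMatrix` therefore carries a ``state`` flag and each
operation in :mod:`mirprospect.normalize` checks it before transforming.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .exceptions import StructuralError

#: Allowed processing states, in their canonical order.
STATES = ("raw", "collapsed", "normalized", "log2")


@dataclass
class ExpressionMatrix:
    """A features x samples intensity matrix.

    Parameters
    ----------
    values
        DataFrame with one row per probe (state ``raw``) or per miRNA
        (later states) and one column per sample. Row and column labels
        must be unique.
    state
        One of :data:`STATES`.
    probe_group
        For ``raw`` matrices only: a Series aligned with ``values.index``
        naming the miRNA each probe replicate collapses to.
    """

    values: pd.DataFrame
    state: str = "raw"
    probe_group: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise StructuralError(f"unknown matrix state {self.state!r}; expected one of {STATES}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise StructuralError(f"duplicate row identifiers: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise StructuralError(f"duplicate sample identifiers: {dups[:5]}")
        if self.probe_group is not None:
            if not self.probe_group.index.equals(self.values.index):
                raise StructuralError("probe_group index does not match the expression rows")

    # -- convenience accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    # -- state handling --------------------------------------------------------
    def require_state(self, *states: str) -> None:
        if self.state not in states:
            raise StructuralError(
                f"operation requires matrix state in {states}, got {self.state!r}"
            )

    def with_values(self, values: pd.DataFrame, state: str) -> "ExpressionMatrix":
        """Return a new matrix with ``values`` and ``state``.

        The probe_group map is only meaningful while replicate probes are
        present, so it is carried over only for ``raw`` outputs.
        """
        pg = self.probe_group if state == "raw" else None
        if pg is not None and not pg.index.equals(values.index):
            pg = pg.reindex(values.index)
        return ExpressionMatrix(values=values, state=state, probe_group=pg)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise StructuralError(f"unknown sample identifiers: {missing[:5]}")
        return ExpressionMatrix(
            values=self.values.loc[:, sample_ids], state=self.state, probe_group=self.probe_group
        )
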