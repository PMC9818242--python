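"""Dense genes × samples containers used throughout plbin.

Two containers cover the whole toolkit: :class:`ExpressionMatrix` holds raw
(continuous or count) measurements, :class:`CategorizedMatrix` holds the
discrete states the implication-network machinery consumes.  Both store a
float ndarray with ``NaN`` marking missing entries, plus ordered, unique
gene and sample identifier lists.

The matrices are deliberately plain dataclasses rather than AnnData/DataFrame
wrappers: every downstream operation is a vectorised numpy computation over
the raw array, and the identifier lists are the only metadata the methods
need.  ``to_frame`` converts to a pandas DataFrame for I/O and interop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError, IdentifierError

OMICS_KINDS = ("mrna", "protein", "cnv", "sc_counts", "generic")

#: states of a ternary categorization: down-regulated / normal / up-regulated
TERNARY_STATES = (-1, 0, 1)
#: states of a binary categorization: not expressed / expressed (low / high)
BINARY_STATES = (0, 1)


def _check_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise IdentifierError(f"duplicate {what} ids: {dupes[:5]}")
    return ids


@dataclass
class ExpressionMatrix:
    """A genes × samples matrix of measurements, missing entries as NaN.

    Parameters
    ----------
    gene_ids, sample_ids
        Unique row / column identifiers.
    values
        Real matrix of shape ``(len(gene_ids), len(sample_ids))``.  Expression
        values are expected on a log scale; CNV matrices hold integer copy
        numbers; ``sc_counts`` matrices hold non-negative feature counts.
    omics_kind
        One of ``mrna | protein | cnv | sc_counts | generic``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    omics_kind: str = "generic"

    def __post_init__(self) -> None:
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise InputError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.omics_kind not in OMICS_KINDS:
            raise InputError(f"unknown omics_kind {self.omics_kind!r}")
        finite = np.isfinite(self.values) | np.isnan(self.values)
        if not finite.all():
            raise InputError("non-missing values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise IdentifierError(f"unknown gene id {gene_id!r}") from None

    def gene_values(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, omics_kind: str = "generic") -> "ExpressionMatrix":
        return cls(
            gene_ids=list(map(str, frame.index)),
            sample_ids=list(map(str, frame.columns)),
            values=frame.to_numpy(dtype=float),
            omics_kind=omics_kind,
        )


@dataclass
class CategorizedMatrix:
    """Discrete gene states: ternary {-1, 0, +1} or binary {0, 1}.

    ``states`` is a float array so NaN can mark missing entries; all
    non-missing entries must lie in the declared state set.  ``provenance``
    records how the states were produced (thresholds, model parameters).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    states: np.ndarray
    arity: int = 3
    provenance: str = ""
    _skip_validation: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise InputError(
                f"states shape {self.states.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.arity not in (2, 3):
            raise InputError(f"arity must be 2 or 3, got {self.arity}")
        if not self._skip_validation:
            allowed = self.state_set
            obs = self.states[~np.isnan(self.states)]
            if obs.size and not np.isin(obs, allowed).all():
                bad = sorted(set(obs[~np.isin(obs, allowed)].tolist()))
                raise InputError(f"states outside {allowed}: {bad[:5]}")

    @property
    def state_set(self) -> tuple[int, ...]:
        return TERNARY_STATES if self.arity == 3 else BINARY_STATES

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_states(self, gene_id: str) -> np.ndarray:
        try:
            idx = self.gene_ids.index(gene_id)
        except ValueError:
            raise IdentifierError(f"unknown gene id {gene_id!r}") from None
        return self.states[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.states, index=self.gene_ids, columns=self.sample_ids)
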