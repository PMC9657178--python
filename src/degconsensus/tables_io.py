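"""Reading, validation and writing of the two-table input dialect.

The pipeline consumes two tab-separated files:

* a **read-counts table**: header row, first column transcript/gene
  identifiers (the first header cell is free text and ignored), remaining
  columns integer read counts, one per sample;
* a **sample-information table**: two columns, ``sample_name`` and
  ``condition``, where ``condition`` takes exactly two values (the two
  experimental groups).

Sample names in the two files are matched case-insensitively by default
because real inputs frequently disagree in capitalization between the count
header and the metadata table; a strict mode is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleInfo",
    "Dataset",
    "ValidationError",
    "parse_counts",
    "parse_sample_info",
    "harmonize",
    "write_counts",
    "write_sample_info",
]


class ValidationError(ValueError):
    """An input table violates the format contract."""


@dataclass(frozen=True)
class CountMatrix:
    """Integer gene x sample count table with ordered, unique names."""

    gene_ids: tuple[str, ...]
    sample_names: tuple[str, ...]
    counts: np.ndarray  # shape (genes, samples), integer dtype

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D array")
        if counts.shape != (len(self.gene_ids), len(self.sample_names)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_names)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise ValidationError(f"duplicate gene id: {dup!r}")
        if len(set(self.sample_names)) != len(self.sample_names):
            dup = _first_duplicate(self.sample_names)
            raise ValidationError(f"duplicate sample name: {dup!r}")
        if len(self.gene_ids) < 1:
            raise ValidationError("count table must contain at least one gene")
        if len(self.sample_names) < 2:
            raise ValidationError("count table must contain at least two sample columns")
        if not np.issubdtype(counts.dtype, np.integer):
            raise ValidationError("counts must be integers")
        if (counts < 0).any():
            g, s = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.gene_ids[g]!r}, sample {self.sample_names[s]!r}"
            )
        object.__setattr__(self, "counts", counts)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.gene_ids), columns=list(self.sample_names)
        )

    def reorder_samples(self, order: Sequence[int]) -> "CountMatrix":
        order = list(order)
        return CountMatrix(
            gene_ids=self.gene_ids,
            sample_names=tuple(self.sample_names[i] for i in order),
            counts=self.counts[:, order],
        )


@dataclass(frozen=True)
class SampleInfo:
    """Ordered sample -> condition mapping with exactly two condition levels."""

    sample_names: tuple[str, ...]
    condition: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sample_names) != len(self.condition):
            raise ValidationError("sample_names and condition must have equal length")
        if len(set(self.sample_names)) != len(self.sample_names):
            dup = _first_duplicate(self.sample_names)
            raise ValidationError(f"duplicate sample name: {dup!r}")
        levels = self.levels
        if len(levels) != 2:
            raise ValidationError(
                f"condition must have exactly two values, found {len(levels)}: {sorted(set(self.condition))}"
            )

    @property
    def levels(self) -> tuple[str, str]:
        """The two condition levels, in first-appearance order."""
        seen: list[str] = []
        for c in self.condition:
            if c not in seen:
                seen.append(c)
        if len(seen) != 2:
            raise ValidationError(
                f"condition must have exactly two values, found {len(seen)}"
            )
        return (seen[0], seen[1])

    def samples_for(self, level: str) -> tuple[str, ...]:
        return tuple(
            s for s, c in zip(self.sample_names, self.condition) if c == level
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_name": list(self.sample_names), "condition": list(self.condition)}
        )


@dataclass(frozen=True)
class Dataset:
    """Harmonized counts + design: columns of ``counts`` follow design order.

    ``condition_order`` is (reference level, treatment level); log2 fold
    changes downstream are treatment over reference.
    """

    counts: CountMatrix
    design: SampleInfo
    condition_order: tuple[str, str]

    def __post_init__(self) -> None:
        if self.counts.sample_names != self.design.sample_names:
            raise ValidationError(
                "counts sample order does not match design order; use harmonize()"
            )
        if set(self.condition_order) != set(self.design.levels):
            raise ValidationError(
                f"condition_order {self.condition_order} does not match design levels "
                f"{self.design.levels}"
            )

    @property
    def reference(self) -> str:
        return self.condition_order[0]

    @property
    def treatment(self) -> str:
        return self.condition_order[1]

    def group_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Column indices of (reference, treatment) samples."""
        cond = np.asarray(self.design.condition)
        return (
            np.flatnonzero(cond == self.reference),
            np.flatnonzero(cond == self.treatment),
        )

    def swap_conditions(self) -> "Dataset":
        return replace(self, condition_order=(self.treatment, self.reference))


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    raise ValueError("no duplicate present")


def parse_counts(path: str | Path) -> CountMatrix:
    """Parse a read-counts TSV into a :class:`CountMatrix`.

    The header's first cell is free text and ignored; every remaining column
    must contain non-negative integers. Row and column order are preserved.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"counts file not found: {path}")
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 3:
        raise ValidationError(
            f"count table needs a gene-id column plus at least 2 sample columns, "
            f"found {df.shape[1]} columns"
        )
    gene_ids = df.iloc[:, 0].astype(str).tolist()
    sample_names = [str(c) for c in df.columns[1:]]
    raw = df.iloc[:, 1:]
    counts = np.empty(raw.shape, dtype=np.int64)
    for j, col in enumerate(raw.columns):
        vals = raw[col]
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise ValidationError(
                f"missing count at row {gene_ids[row]!r}, column {col!r}"
            )
        numeric = pd.to_numeric(vals, errors="coerce")
        if numeric.isna().any():
            row = int(numeric.index[numeric.isna()][0])
            raise ValidationError(
                f"non-numeric count {vals.iloc[row]!r} at row {gene_ids[row]!r}, column {col!r}"
            )
        frac = numeric.astype(float) % 1
        if (frac != 0).any():
            row = int(numeric.index[frac != 0][0])
            raise ValidationError(
                f"non-integer count {vals.iloc[row]!r} at row {gene_ids[row]!r}, column {col!r}"
            )
        if (numeric < 0).any():
            row = int(numeric.index[numeric < 0][0])
            raise ValidationError(
                f"negative count at row {gene_ids[row]!r}, column {col!r}"
            )
        counts[:, j] = numeric.astype(np.int64).to_numpy()
    return CountMatrix(
        gene_ids=tuple(gene_ids), sample_names=tuple(sample_names), counts=counts
    )


def parse_sample_info(path: str | Path) -> SampleInfo:
    """Parse a sample-information TSV into a :class:`SampleInfo`.

    The second column header must read ``condition`` (case-insensitive); the
    column must take exactly two distinct values.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"sample info file not found: {path}")
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] != 2:
        raise ValidationError(
            f"sample info table must have exactly 2 columns, found {df.shape[1]}"
        )
    header2 = str(df.columns[1]).strip().strip("*").strip()
    if header2.lower() != "condition":
        raise ValidationError(
            f'second column must be headed "condition", found {df.columns[1]!r}'
        )
    names = [str(s).strip().strip("*").strip() for s in df.iloc[:, 0]]
    cond = [str(c) for c in df.iloc[:, 1]]
    info = SampleInfo(sample_names=tuple(names), condition=tuple(cond))
    _warn_on_name_convention(info)
    return info


def _warn_on_name_convention(info: SampleInfo) -> None:
    # Convention (not a requirement): sample name = condition + replicate number.
    for s, c in zip(info.sample_names, info.condition):
        if not s.lower().startswith(c.lower()):
            warnings.warn(
                f"sample name {s!r} does not start with its condition {c!r}; "
                "this is a naming convention only and does not affect results",
                UserWarning,
                stacklevel=3,
            )
            return


def harmonize(
    counts: CountMatrix,
    design: SampleInfo,
    reference: str | None = None,
    strict_names: bool = False,
) -> Dataset:
    """Align count columns to the design's sample order and fix the baseline.

    Matching between the count header and the design's ``sample_name`` column
    is case-insensitive unless ``strict_names`` is set; a warning is emitted
    whenever a match needed case folding. The reference (denominator)
    condition defaults to the first level in design file order and can be
    overridden with ``reference``.
    """
    if strict_names:
        lookup = {s: i for i, s in enumerate(counts.sample_names)}

        def find(name: str) -> int:
            if name not in lookup:
                raise ValidationError(
                    f"design sample {name!r} not found in count columns"
                )
            return lookup[name]

    else:
        folded: dict[str, list[int]] = {}
        for i, s in enumerate(counts.sample_names):
            folded.setdefault(s.lower(), []).append(i)
        ambiguous = [k for k, v in folded.items() if len(v) > 1]
        case_warned = False

        def find(name: str) -> int:
            nonlocal case_warned
            key = name.lower()
            if key in ambiguous:
                raise ValidationError(
                    f"design sample {name!r} matches multiple count columns case-insensitively"
                )
            if key not in folded:
                raise ValidationError(
                    f"design sample {name!r} not found in count columns"
                )
            idx = folded[key][0]
            if counts.sample_names[idx] != name and not case_warned:
                warnings.warn(
                    f"sample names matched case-insensitively "
                    f"({counts.sample_names[idx]!r} ~ {name!r})",
                    UserWarning,
                    stacklevel=2,
                )
                case_warned = True
            return idx

    order = [find(name) for name in design.sample_names]
    if len(set(order)) != len(order):
        raise ValidationError("two design samples matched the same count column")
    if len(order) != counts.n_samples:
        missing = sorted(set(range(counts.n_samples)) - set(order))
        names = [counts.sample_names[i] for i in missing]
        raise ValidationError(f"count columns absent from design: {names}")
    reordered = CountMatrix(
        gene_ids=counts.gene_ids,
        sample_names=design.sample_names,
        counts=counts.counts[:, order],
    )
    levels = design.levels
    if reference is None:
        condition_order = levels
    else:
        if reference not in levels:
            raise ValidationError(
                f"reference condition {reference!r} is not a design level {levels}"
            )
        other = levels[1] if reference == levels[0] else levels[0]
        condition_order = (reference, other)
    return Dataset(counts=reordered, design=design, condition_order=condition_order)


def write_counts(cm: CountMatrix, path: str | Path, id_header: str = "gene_id") -> None:
    """Write a CountMatrix in the input dialect (round-trips exactly)."""
    df = cm.to_frame()
    df.index.name = id_header
    df.to_csv(path, sep="\t")


def write_sample_info(info: SampleInfo, path: str | Path) -> None:
    info.to_frame().to_csv(path, sep="\t", index=False)
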