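"""Consensus stage: per-method DEG sets, intersection, Venn partition.

The consensus of k selected methods is the intersection of their DEG sets.
Thresholds (|log2fc| >= lfc_cut and fdr < fdr_cut) are applied per method
*before* intersecting, so the displayed table and the intersection agree.
A gene whose per-method regulatory statuses disagree is labelled
``Inconsistent``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engines import DEResult

__all__ = [
    "DEGSet",
    "deg_set",
    "consensus_table",
    "venn_counts",
    "write_venn_counts",
    "venn_plot",
]

CONSENSUS_INCONSISTENT = "Inconsistent"
MAX_METHODS = 4


@dataclass(frozen=True)
class DEGSet:
    """Genes passing one method's thresholds, with their statuses."""

    method: str
    genes: frozenset[str]
    status: Mapping[str, str]  # gene -> up/down/zero_value
    universe: frozenset[str]  # tested genes (post expression filter)

    def __post_init__(self) -> None:
        if not self.genes <= self.universe:
            raise ValueError("DEG set must be a subset of the tested universe")
        if set(self.status) != set(self.genes):
            raise ValueError("status must cover exactly the DEG set")


def deg_set(result: DEResult, lfc_cut: float = 2.0, fdr_cut: float = 0.01) -> DEGSet:
    """Threshold one method's result: |log2fc| >= lfc_cut and fdr < fdr_cut.

    The fold-change cut is inclusive (a gene at exactly the cut is kept);
    the fdr cut is strict.
    """
    if lfc_cut < 0:
        raise ValueError("lfc_cut must be >= 0")
    if not 0 < fdr_cut <= 1:
        raise ValueError("fdr_cut must lie in (0, 1]")
    t = result.table
    mask = (t["log2fc"].abs() >= lfc_cut) & (t["fdr"] < fdr_cut)
    sel = t.index[mask]
    return DEGSet(
        method=result.method,
        genes=frozenset(sel),
        status={g: t.at[g, "status"] for g in sel},
        universe=frozenset(t.index),
    )


def consensus_table(
    sets: Sequence[DEGSet], results: Sequence[DEResult]
) -> pd.DataFrame:
    """Final intersection table over the selected methods.

    Columns, in order: consensus status (common status or ``Inconsistent``),
    mean and sample SD of the selected methods' log2fc (SD is NA for a
    single method), one log2fc column per method, then one fdr/probability
    column per method last. Index: gene id. Gene order follows the first
    method's result table.
    """
    if not sets:
        raise ValueError("at least one method must be selected")
    if len(sets) != len(results) or any(
        s.method != r.method for s, r in zip(sets, results)
    ):
        raise ValueError("sets and results must match one-to-one by method")
    common = set(sets[0].genes)
    for s in sets[1:]:
        common &= s.genes
    ordered = [g for g in results[0].table.index if g in common]

    rows: dict[str, list] = {"status": []}
    lfc_cols = {s.method: [] for s in sets}
    fdr_cols = {s.method: [] for s in sets}
    means, sds = [], []
    for g in ordered:
        statuses = {s.status[g] for s in sets}
        rows["status"].append(
            statuses.pop() if len(statuses) == 1 else CONSENSUS_INCONSISTENT
        )
        lfcs = []
        for s, r in zip(sets, results):
            lfc = float(r.table.at[g, "log2fc"])
            lfcs.append(lfc)
            lfc_cols[s.method].append(lfc)
            fdr_cols[s.method].append(float(r.table.at[g, "fdr"]))
        means.append(float(np.mean(lfcs)))
        sds.append(float(np.std(lfcs, ddof=1)) if len(lfcs) > 1 else np.nan)

    out = pd.DataFrame(index=pd.Index(ordered, name="gene_id"))
    out["status"] = rows["status"]
    out["mean_log2fc"] = means
    out["sd_log2fc"] = sds
    for s in sets:
        out[f"log2fc_{s.method}"] = lfc_cols[s.method]
    for s in sets:
        out[f"fdr_{s.method}"] = fdr_cols[s.method]
    return out


def venn_counts(sets: Sequence[DEGSet]) -> dict[tuple[bool, ...], int]:
    """Exact region counts for the 2^k - 1 non-empty membership patterns.

    Keys are membership tuples aligned with ``sets`` (True = gene belongs to
    that method's DEG set); the all-True region equals the consensus.
    """
    if not sets:
        raise ValueError("at least one set required")
    if len(sets) > MAX_METHODS:
        raise ValueError(f"at most {MAX_METHODS} sets supported")
    union: set[str] = set()
    for s in sets:
        union |= s.genes
    counts = {
        pattern: 0
        for pattern in product([False, True], repeat=len(sets))
        if any(pattern)
    }
    for g in union:
        pattern = tuple(g in s.genes for s in sets)
        counts[pattern] += 1
    return counts


def write_venn_counts(
    counts: dict[tuple[bool, ...], int], methods: Sequence[str], path: str | Path
) -> None:
    rows = []
    for pattern, n in sorted(counts.items(), reverse=True):
        label = "&".join(m for m, inc in zip(methods, pattern) if inc)
        rows.append({"region": label, "pattern": "".join("1" if b else "0" for b in pattern), "count": n})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def venn_plot(sets: Sequence[DEGSet], path: str | Path) -> None:
    """Proportional-free Venn diagram for 2 or 3 DEG sets.

    Region counts for 4 methods are available through :func:`venn_counts`;
    a 4-set diagram is not drawn.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    k = len(sets)
    if k not in (2, 3):
        raise ValueError("venn_plot supports 2 or 3 sets; use venn_counts for others")
    counts = venn_counts(sets)
    fig, ax = plt.subplots(figsize=(5, 5))
    if k == 2:
        centers = [(-0.5, 0.0), (0.5, 0.0)]
        label_pos = {(True, False): (-1.0, 0), (False, True): (1.0, 0), (True, True): (0, 0)}
    else:
        centers = [(-0.5, -0.3), (0.5, -0.3), (0.0, 0.6)]
        label_pos = {
            (True, False, False): (-1.0, -0.5),
            (False, True, False): (1.0, -0.5),
            (False, False, True): (0.0, 1.1),
            (True, True, False): (0.0, -0.5),
            (True, False, True): (-0.6, 0.35),
            (False, True, True): (0.6, 0.35),
            (True, True, True): (0.0, 0.0),
        }
    for (cx, cy), s in zip(centers, sets):
        ax.add_patch(Circle((cx, cy), 1.0, alpha=0.3, label=s.method))
        ax.annotate(s.method, (cx, cy + 1.05), ha="center")
    for pattern, (x, y) in label_pos.items():
        ax.annotate(str(counts[pattern]), (x, y), ha="center", va="center")
    ax.set_xlim(-2.2, 2.2)
    ax.set_ylim(-2.2, 2.2)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=120)
    plt.close(fig)
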