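"""Seeded two-condition negative-binomial count simulator with known truth.

The generator emulates a bulk RNA-seq comparison between two sample groups:
per-gene baseline means are log-normal, true-DE genes (an exactly realized
fraction of the genes) shift their condition means symmetrically by
2^(+lfc/2) and 2^(-lfc/2) so library sizes stay comparable, per-sample
library-size factors are uniform on a configurable range, and counts are NB
with Var = mu + phi * mu^2 (Poisson when phi = 0).

Draw order (single NumPy PCG64 stream seeded from ``seed``): (1) baseline
log-means, (2) DE gene positions by permutation, (3) up/down signs,
(4) library factors per sample reference-first, (5) the count matrix
gene-major. The same seed reproduces the output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluate import DIRECTION_DOWN, DIRECTION_NA, DIRECTION_UP, GoldStandard, write_gold_standard
from .tables_io import CountMatrix, Dataset, SampleInfo, write_counts, write_sample_info

__all__ = ["SimDesign", "SimTruth", "simulate_dataset", "write_simulation", "design_from_file"]


@dataclass(frozen=True)
class SimDesign:
    """Parameters of the synthetic two-condition experiment.

    Defaults describe a moderately deep bulk experiment: 2000 genes, five
    replicates per condition, 10% true DEGs at |log2FC| = 2, NB dispersion
    0.1, library-size factors within +/-30% of each other.
    """

    G: int = 2000
    n_ref: int = 5
    n_trt: int = 5
    pi_de: float = 0.1
    lfc_magnitude: float = 2.0
    mean_log_mu: float = 4.0
    sd_log_mu: float = 1.5
    dispersion: float = 0.1
    libsize_range: tuple[float, float] = (0.7, 1.3)
    seed: int = 0
    ref_label: str = "control"
    trt_label: str = "treated"

    def __post_init__(self) -> None:
        if self.G < 1 or self.n_ref < 1 or self.n_trt < 1:
            raise ValueError("G, n_ref, n_trt must be >= 1")
        if not 0.0 <= self.pi_de <= 1.0:
            raise ValueError("pi_de must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        lo, hi = self.libsize_range
        if not (0 < lo <= hi):
            raise ValueError("libsize_range must be positive and ordered")
        if self.lfc_magnitude < 0:
            raise ValueError("lfc_magnitude must be >= 0")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth per gene: DE flag, signed log2FC, mean, dispersion."""

    gene_ids: tuple[str, ...]
    is_de: np.ndarray
    log2fc: np.ndarray
    baseline_mean: np.ndarray
    dispersion: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "is_de": self.is_de.astype(int),
                "true_log2fc": self.log2fc,
                "baseline_mean": self.baseline_mean,
                "dispersion": self.dispersion,
            },
            index=pd.Index(self.gene_ids, name="gene_id"),
        )

    def gold_standard(self) -> GoldStandard:
        is_deg = {}
        direction = {}
        for g, de, lfc in zip(self.gene_ids, self.is_de, self.log2fc):
            is_deg[g] = bool(de)
            direction[g] = (
                (DIRECTION_UP if lfc > 0 else DIRECTION_DOWN) if de else DIRECTION_NA
            )
        return GoldStandard(is_deg=is_deg, direction=direction)


def simulate_dataset(design: SimDesign) -> tuple[Dataset, SimTruth]:
    """Generate a harmonized Dataset plus its ground truth."""
    rng = np.random.default_rng(design.seed)
    G = design.G

    mu = np.exp(rng.normal(design.mean_log_mu, design.sd_log_mu, size=G))

    n_de = round(G * design.pi_de)
    de_pos = rng.permutation(G)[:n_de]
    is_de = np.zeros(G, dtype=bool)
    is_de[de_pos] = True

    # signs balanced up/down up to rounding
    n_up = n_de // 2 + (n_de % 2)
    signs = np.array([1.0] * n_up + [-1.0] * (n_de - n_up))
    signs = rng.permutation(signs)
    log2fc = np.zeros(G)
    log2fc[de_pos] = signs * design.lfc_magnitude

    n_samples = design.n_ref + design.n_trt
    lib = rng.uniform(*design.libsize_range, size=n_samples)

    # condition means: symmetric split 2^(+lfc/2) / 2^(-lfc/2)
    mean_ref = mu * 2.0 ** (-log2fc / 2.0)
    mean_trt = mu * 2.0 ** (+log2fc / 2.0)

    cond_mean = np.concatenate(
        [
            np.repeat(mean_ref[:, None], design.n_ref, axis=1),
            np.repeat(mean_trt[:, None], design.n_trt, axis=1),
        ],
        axis=1,
    )
    means = cond_mean * lib[None, :]
    phi = design.dispersion
    if phi == 0:
        counts = rng.poisson(means).astype(np.int64)
    else:
        r = 1.0 / phi
        counts = rng.negative_binomial(r, r / (r + means)).astype(np.int64)

    gene_ids = tuple(f"gene{str(i + 1).zfill(len(str(G)))}" for i in range(G))
    sample_names = tuple(
        [f"{design.ref_label}{i + 1}" for i in range(design.n_ref)]
        + [f"{design.trt_label}{i + 1}" for i in range(design.n_trt)]
    )
    condition = tuple(
        [design.ref_label] * design.n_ref + [design.trt_label] * design.n_trt
    )
    cm = CountMatrix(gene_ids=gene_ids, sample_names=sample_names, counts=counts)
    info = SampleInfo(sample_names=sample_names, condition=condition)
    ds = Dataset(
        counts=cm, design=info, condition_order=(design.ref_label, design.trt_label)
    )
    truth = SimTruth(
        gene_ids=gene_ids,
        is_de=is_de,
        log2fc=log2fc,
        baseline_mean=mu,
        dispersion=np.full(G, phi),
    )
    return ds, truth


def write_simulation(ds: Dataset, truth: SimTruth, outdir: str | Path) -> dict[str, Path]:
    """Emit cts.tsv / coldata.tsv (input dialect), truth.tsv and gold.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "cts.tsv",
        "coldata": outdir / "coldata.tsv",
        "truth": outdir / "truth.tsv",
        "gold": outdir / "gold.tsv",
    }
    write_counts(ds.counts, paths["counts"])
    write_sample_info(ds.design, paths["coldata"])
    truth.to_frame().to_csv(paths["truth"], sep="\t")
    write_gold_standard(truth.gold_standard(), paths["gold"])
    return paths


def design_from_file(path: str | Path) -> SimDesign:
    """Load a SimDesign from YAML or flat ``key=value`` lines."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError
    except Exception:
        data = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            data[k.strip()] = yaml.safe_load(v.strip())
    if "libsize_range" in data and isinstance(data["libsize_range"], list):
        data["libsize_range"] = tuple(data["libsize_range"])
    return SimDesign(**data)
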