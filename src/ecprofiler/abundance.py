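"""Length-normalized per-million abundance profiles over EC bins.

Raw assigned-ORF counts are a biased proxy for enzyme abundance: long
proteins shed more reads. Borrowing the transcripts-per-million idea from
RNA-seq, each bin's count r_b is divided by the bin's effective protein
length

    e_b = p_b - rl/3 + 1

(p_b the mean protein length of the bin in amino acids, rl the sample's
mean read length in base pairs — rl/3 converts read length to residues, +1
counts the distinct start positions), then rescaled so every sample sums to
one million:

    rho_b = (r_b / e_b) * 1e6 / sum_b (r_b / e_b)

The fixed per-sample total makes profiles directly comparable across
samples and sequencing depths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .reference_db import GoldStandard

SCALE = 1e6


class ParameterError(ValueError):
    pass


@dataclass
class CountTable:
    """Raw per-sample assigned-ORF counts per EC, plus per-sample read stats."""

    counts: pd.DataFrame  # index: EC labels, columns: samples, non-negative ints
    read_length: pd.Series  # mean input read length (bp) per sample
    unassigned: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.read_length.index)
        if missing:
            raise ValueError(f"read_length missing for samples: {sorted(missing)}")

    @property
    def total_assigned(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class AbundanceProfile:
    """Effective counts per million (rho) per EC bin and sample."""

    rho: pd.DataFrame  # index: EC, columns: samples
    effective_length: pd.DataFrame  # e_b per EC and sample (rl varies by sample)
    raw: pd.DataFrame | None = None


def effective_length(p_b: float, rl: float) -> float:
    """Effective protein length e_b = p_b - rl/3 + 1, clamped below at 1."""
    if p_b <= 0 or rl <= 0:
        raise ParameterError(f"p_b and rl must be positive, got p_b={p_b}, rl={rl}")
    return max(p_b - rl / 3.0 + 1.0, 1.0)


def normalize(
    counts: CountTable,
    gold: GoldStandard | dict[str, float],
    method: str = "ecpm",
) -> AbundanceProfile:
    """Convert raw counts into effective counts per million.

    ``gold`` supplies the per-EC mean protein lengths p_b (either a curated
    GoldStandard or a plain {ec: p_b} mapping). The default method ("ecpm")
    is the per-million normalization above; "rpk" (counts per kilobase of
    protein, no per-million rescale) and "raw" are available for comparison
    experiments only. A sample with zero assigned ORFs yields an all-zero
    column with a warning.
    """
    p_b = gold.mean_protein_length if isinstance(gold, GoldStandard) else dict(gold)
    unknown = [ec for ec in counts.counts.index if ec not in p_b]
    if unknown:
        raise KeyError(f"no reference protein length for EC bins: {unknown[:5]}")
    ecs = list(counts.counts.index)
    samples = list(counts.counts.columns)
    pb_vec = np.array([p_b[ec] for ec in ecs], dtype=float)
    e = pd.DataFrame(
        {
            s: [effective_length(p, float(counts.read_length[s])) for p in pb_vec]
            for s in samples
        },
        index=ecs,
    )
    r = counts.counts.astype(float)
    rate = r / e
    if method == "raw":
        rho = r.copy()
    elif method == "rpk":
        rho = rate * 1000.0 / 3.0  # counts per kilobase of coding sequence
    elif method == "ecpm":
        totals = rate.sum(axis=0)
        zero = totals[totals == 0].index.tolist()
        if zero:
            warnings.warn(f"samples with zero assigned ORFs: {zero}", stacklevel=2)
        safe = totals.replace(0.0, np.nan)
        rho = (rate * SCALE).div(safe, axis=1).fillna(0.0)
    else:
        raise ParameterError(f"unknown normalization method {method!r}")
    return AbundanceProfile(rho=rho, effective_length=e, raw=counts.counts.copy())


# ---------------------------------------------------------------------------
# persistence: TSV matrices, rows = EC labels, columns = samples


def write_matrix(
    df: pd.DataFrame,
    path: str | Path,
    header_comments: list[str] | None = None,
    index_label: str = "ec",
) -> None:
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index_label=index_label, lineterminator="\n")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)
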