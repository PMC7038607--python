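"""Synthetic fixtures with known ground truth for end-to-end evaluation.

Three generators emulate the data the pipeline consumes:

* protein families — one uniform-random ancestor per (fictional) EC label,
  members derived by i.i.d. per-site substitution at a configurable
  divergence, so within-family identity is controlled and cross-family
  identity sits at the 1/20 background;
* shotgun reads — proteins back-translated with uniformly random synonymous
  codons (bacterial code), fragmented at uniform start positions, strand
  flipped with probability 1/2, and corrupted with i.i.d. substitution
  errors; a truth table maps every read to its source EC;
* two-group cohorts — per-EC baseline abundances drawn log-normal, per
  sample counts drawn negative-binomial around the baseline (overdispersed,
  like real metagenomic counts), with a planted set of ECs whose case-group
  mean is multiplied by a known fold change.

Synthetic EC labels live in the 9.x.y.z range so they cannot collide with
real enzyme classes. Everything is deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .lsh import ALPHABET
from .orf import Read
from .reference_db import GoldStandard, ProteinRecord


@dataclass
class SimulationConfig:
    n_ecs: int = 20
    family_size: int = 8
    length_range: tuple[int, int] = (150, 300)  # amino acids, inclusive
    divergence: float = 0.15  # per-site substitution prob from the ancestor
    read_length: int = 150  # bp
    reads_per_sample: int = 2000
    error_rate: float = 0.001  # per-base substitution errors
    codon_table: int = 11
    n_samples_per_group: int = 20
    n_planted: int = 10
    fold_change: float = 4.0
    dispersion: float = 0.3  # negative-binomial: var = mu + dispersion * mu^2
    baseline_log_mean: float = np.log(100.0)
    baseline_log_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.divergence, self.error_rate):
            if not 0.0 <= p < 1.0:
                raise ValueError(f"probabilities must lie in [0, 1), got {p}")
        for n in (self.n_ecs, self.family_size, self.read_length, self.reads_per_sample):
            if n <= 0:
                raise ValueError("counts must be positive")


def synthetic_ec_label(i: int) -> str:
    """The i-th fictional EC label in the reserved 9.x.y.z namespace."""
    return f"9.{1 + i // 100}.{1 + (i // 10) % 10}.{1 + i % 10}"


def simulate_protein_families(cfg: SimulationConfig) -> tuple[GoldStandard, dict[str, str]]:
    """Draw one ancestor per EC and mutate family members off it.

    Substituted residues are uniform over the 19 alternatives, so expected
    pairwise identity between two members is (1-d)^2 + d^2/19 per site.
    Returns the gold-standard-shaped corpus and the {ec: ancestor} truth.
    """
    rng = np.random.default_rng(cfg.seed)
    aa = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
    records: list[ProteinRecord] = []
    truth: dict[str, str] = {}
    lo, hi = cfg.length_range
    for i in range(cfg.n_ecs):
        ec = synthetic_ec_label(i)
        length = int(rng.integers(lo, hi + 1))
        ancestor = aa[rng.integers(0, 20, size=length)]
        truth[ec] = ancestor.tobytes().decode()
        for j in range(cfg.family_size):
            member = ancestor.copy()
            mut = rng.random(length) < cfg.divergence
            if mut.any():
                # draw a uniform alternative: shift by 1..19 ranks mod 20
                shift = rng.integers(1, 20, size=int(mut.sum()))
                ranks = np.searchsorted(aa, member[mut])
                member[mut] = aa[(ranks + shift) % 20]
            records.append(
                ProteinRecord(
                    id=f"{ec}|m{j}",
                    sequence=member.tobytes().decode(),
                    ec_labels=[ec],
                    reviewed=True,
                    evidence="protein-level",
                )
            )
    return GoldStandard(records=records), truth


def _codons_by_aa(table: int) -> dict[str, list[str]]:
    tbl = CodonTable.unambiguous_dna_by_id[table]
    out: dict[str, list[str]] = {}
    for codon, aa in sorted(tbl.forward_table.items()):
        out.setdefault(aa, []).append(codon)
    return out


def back_translate(protein: str, rng: np.random.Generator, table: int = 11) -> str:
    """Back-translate with uniformly random synonymous codons."""
    codons = _codons_by_aa(table)
    return "".join(codons[aa][rng.integers(0, len(codons[aa]))] for aa in protein)


_NT = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = dict(zip(b"ACGT", b"TGCA"))


def simulate_reads(
    gold: GoldStandard,
    weights: dict[str, float] | None,
    cfg: SimulationConfig,
    seed: int | None = None,
) -> tuple[list[Read], pd.DataFrame]:
    """Sample reads from back-translated proteins, weighted per protein.

    ``weights`` maps protein id -> sampling weight (uniform when None).
    Each read is a uniform substring of length ``read_length`` of the
    back-translated coding sequence, reverse-complemented with probability
    1/2, with i.i.d. substitution errors; the truth table records read id,
    source protein, and source EC. Proteins too short for a full read are
    skipped with a warning.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    usable = [r for r in gold.records if 3 * len(r.sequence) >= cfg.read_length]
    skipped = len(gold.records) - len(usable)
    if skipped:
        import warnings

        warnings.warn(f"{skipped} proteins shorter than one read were skipped", stacklevel=2)
    if not usable:
        raise ValueError("no protein long enough for the requested read length")
    w = np.array([1.0 if weights is None else weights.get(r.id, 0.0) for r in usable])
    if w.sum() <= 0:
        raise ValueError("weights must be non-negative and not all zero")
    w = w / w.sum()
    reads: list[Read] = []
    rows = []
    picks = rng.choice(len(usable), size=cfg.reads_per_sample, p=w)
    for ridx, pick in enumerate(picks):
        rec = usable[pick]
        cds = back_translate(rec.sequence, rng, cfg.codon_table)
        start = int(rng.integers(0, len(cds) - cfg.read_length + 1))
        frag = np.frombuffer(cds[start : start + cfg.read_length].encode(), dtype=np.uint8).copy()
        if rng.random() < 0.5:
            frag = np.array([_COMPLEMENT[b] for b in frag[::-1]], dtype=np.uint8)
            strand = "-"
        else:
            strand = "+"
        err = rng.random(cfg.read_length) < cfg.error_rate
        if err.any():
            shift = rng.integers(1, 4, size=int(err.sum()))
            ranks = np.searchsorted(_NT, frag[err])
            frag[err] = _NT[(ranks + shift) % 4]
        rid = f"read{ridx}"
        reads.append(Read(rid, frag.tobytes().decode(), "I" * cfg.read_length))
        rows.append((rid, rec.id, rec.ec_labels[0], strand, start))
    truth = pd.DataFrame(rows, columns=["read_id", "protein_id", "ec", "strand", "start"])
    return reads, truth


def write_fastq(reads: list[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality or 'I' * len(r.sequence)}\n")


@dataclass
class CohortTruth:
    planted: list[str]
    directions: dict[str, int]  # +1: up in case group
    fold_change: float


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_cohort(
    cfg: SimulationConfig, seed: int | None = None, ec_labels: list[str] | None = None
) -> tuple[pd.DataFrame, pd.Series, CohortTruth]:
    """One two-group cohort of overdispersed per-EC count profiles.

    Baseline abundances are log-normal across ECs; per-sample counts are
    negative-binomial around the baseline with the configured dispersion;
    the first ``n_planted`` ECs have their case-group mean multiplied by
    ``fold_change``. Returns (counts ECs x samples, group labels, truth).
    Two cohorts of the same experiment are generated by calling this twice
    with different seeds: the planted set is identical, the data independent.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    ecs = ec_labels or [synthetic_ec_label(i) for i in range(cfg.n_ecs)]
    if cfg.n_planted > len(ecs):
        raise ValueError("cannot plant more features than ECs simulated")
    planted = ecs[: cfg.n_planted]
    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sigma, size=len(ecs))
    n = cfg.n_samples_per_group
    samples, labels, cols = [], [], {}
    for g, gname in enumerate(("control", "case")):
        mu = baseline.copy()
        if g == 1:
            mu[: cfg.n_planted] *= cfg.fold_change
        for s in range(n):
            name = f"{gname}{s}"
            cols[name] = _nb_draw(rng, mu, cfg.dispersion)
            samples.append(name)
            labels.append(gname)
    counts = pd.DataFrame(cols, index=ecs)
    groups = pd.Series(labels, index=samples, name="group")
    truth = CohortTruth(planted=list(planted), directions={e: 1 for e in planted}, fold_change=cfg.fold_change)
    return counts, groups, truth
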