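"""Pathway aggregation: summed EC abundances and pathway coverage.

A pathway's abundance in a sample is the plain sum of its member ECs'
effective counts per million; an EC belonging to several pathways
contributes to each (standard pathway-mapping behavior). Coverage is the
fraction of a pathway's reference ECs that were detected at all.
The EC-to-pathway map is user-supplied (licensing prevents bundling a real
reference map); a small fictional map ships with the test suite.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .reference_db import parse_ec


@dataclass
class PathwayMap:
    members: dict[str, frozenset[str]]  # pathway id -> member EC labels
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, ecs in self.members.items():
            if not ecs:
                raise ValueError(f"pathway {pid} has no member ECs")
            for ec in ecs:
                if not parse_ec(ec).complete:
                    raise ValueError(f"pathway {pid}: member EC {ec} is not complete")


@dataclass
class PathwayProfile:
    abundance: pd.DataFrame  # index: pathway id, columns: samples
    coverage: pd.Series  # fraction of reference ECs detected, per pathway


def read_pathway_map(path: str | Path) -> PathwayMap:
    """Read a `pathway_id<TAB>pathway_name<TAB>ec` membership table."""
    members: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"pathway_id", "pathway_name", "ec"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"pathway map TSV must have columns {sorted(required)}")
        for row in reader:
            members.setdefault(row["pathway_id"], set()).add(row["ec"])
            names[row["pathway_id"]] = row["pathway_name"]
    return PathwayMap({p: frozenset(e) for p, e in members.items()}, names)


def pathway_abundance(rho: pd.DataFrame, pmap: PathwayMap) -> PathwayProfile:
    """Sum member-EC abundances per pathway; absent ECs count as zero.

    ``rho`` is an EC x sample abundance matrix. Coverage here is computed
    from which ECs are nonzero in at least one sample; use
    :func:`pathway_coverage` directly for a specific detected set.
    """
    if not pmap.members:
        raise ValueError("pathway map is empty")
    rows = {}
    for pid in sorted(pmap.members):
        present = [ec for ec in pmap.members[pid] if ec in rho.index]
        rows[pid] = rho.loc[present].sum(axis=0) if present else pd.Series(0.0, index=rho.columns)
    abundance = pd.DataFrame(rows).T
    abundance.index.name = "pathway"
    detected = set(rho.index[(rho > 0).any(axis=1)])
    return PathwayProfile(abundance=abundance, coverage=pathway_coverage(detected, pmap))


def pathway_coverage(detected_ecs: set[str], pmap: PathwayMap) -> pd.Series:
    """|detected ∩ members| / |members| for every pathway."""
    if not pmap.members:
        raise ValueError("pathway map is empty")
    frac = {
        pid: len(detected_ecs & ecs) / len(ecs) for pid, ecs in sorted(pmap.members.items())
    }
    return pd.Series(frac, name="coverage")
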