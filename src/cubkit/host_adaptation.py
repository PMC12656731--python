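"""Codon adaptation index against host codon-usage tables.

Relative adaptiveness w follows Sharp & Li: within each synonymous family
the most used host codon gets w = 1 and every synonym its usage relative
to that maximum. CAI of a gene is the geometric mean of w over its scored
codons (stops, Met and Trp excluded), computed in log space so long genes
cannot underflow. Host codons the reference never uses receive a small
floor (default 0.01) instead of w = 0, which would annihilate the
geometric mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genetic_code import SCORED_CODONS, SYN_FAMILIES
from .seq_io import CodingSequence, CubkitError, HostCodonUsageTable


@dataclass(frozen=True)
class RelativeAdaptiveness:
    """Per-codon w values for one host, max 1 within each family."""

    host: str
    w: Mapping[str, float]
    floor: float
    smoothed_codons: tuple[str, ...] = ()

    @property
    def smoothing_applied(self) -> bool:
        return bool(self.smoothed_codons)


@dataclass(frozen=True)
class CAIResult:
    """Codon adaptation index of one sequence against one host."""

    id: str
    host: str
    region: str
    cai: float
    n_scored: int


def relative_adaptiveness(
    host_table: HostCodonUsageTable, floor: float = 0.01
) -> RelativeAdaptiveness:
    """Sharp–Li relative adaptiveness from a host usage table.

    Only the 59 scored codons receive w values. A family in which the host
    uses no codon at all cannot be scored and raises an error naming the
    amino acid; individual zero-usage codons get the configurable floor
    and are flagged.
    """
    if not 0 < floor < 1:
        raise CubkitError(f"smoothing floor must be in (0, 1), got {floor}")
    w: dict[str, float] = {}
    smoothed: list[str] = []
    for aa, codons in SYN_FAMILIES.items():
        usage = {c: float(host_table.weights[c]) for c in codons}
        top = max(usage.values())
        if top == 0:
            raise CubkitError(
                f"host {host_table.host!r}: all-zero usage for family {aa}"
            )
        for c, u in usage.items():
            val = u / top
            if val == 0:
                val = floor
                smoothed.append(c)
            w[c] = val
    return RelativeAdaptiveness(
        host=host_table.host, w=w, floor=floor, smoothed_codons=tuple(sorted(smoothed))
    )


def cai(cds: CodingSequence, w: RelativeAdaptiveness) -> CAIResult:
    """CAI = exp(mean log w) over the sequence's scored codons."""
    scored = set(SCORED_CODONS)
    logs = [math.log(w.w[c]) for c in cds.codons if c in scored]
    if not logs:
        raise CubkitError(f"{cds.id}: no scorable codons for CAI")
    return CAIResult(
        id=cds.id,
        host=w.host,
        region=cds.region,
        cai=math.exp(sum(logs) / len(logs)),
        n_scored=len(logs),
    )


def cai_table(
    seqs: Sequence[CodingSequence],
    host_tables: Sequence[HostCodonUsageTable],
    floor: float = 0.01,
) -> pd.DataFrame:
    """Per-sequence CAI against every host table."""
    ws = [relative_adaptiveness(t, floor=floor) for t in host_tables]
    rows = []
    for s in seqs:
        for w in ws:
            r = cai(s, w)
            rows.append(
                {"id": s.id, "seq_host": s.host, "region": s.region,
                 "ref_host": w.host, "cai": r.cai, "n_scored": r.n_scored}
            )
    return pd.DataFrame(rows)


def host_ranking(
    seqs: Sequence[CodingSequence],
    host_tables: Sequence[HostCodonUsageTable],
    group_by_region: bool = True,
    floor: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean/min/max CAI per reference host (optionally per region) and the
    overall host ranking.

    Hosts are ranked by mean CAI over all sequences, descending; ties break
    by host name so the ordering is deterministic.
    """
    if not host_tables:
        raise CubkitError("at least one host table required")
    tab = cai_table(seqs, host_tables, floor=floor)
    keys = ["ref_host", "region"] if group_by_region else ["ref_host"]
    summary = (
        tab.groupby(keys, sort=True)["cai"]
        .agg(mean_cai="mean", min_cai="min", max_cai="max", n="count")
        .reset_index()
    )
    overall = (
        tab.groupby("ref_host", sort=True)["cai"].mean().reset_index(name="mean_cai")
    )
    overall = overall.sort_values(
        ["mean_cai", "ref_host"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    overall["rank"] = np.arange(1, len(overall) + 1)
    return summary, overall
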