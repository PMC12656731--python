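"""Codon counting, RSCU, over/under-representation calls, and Wright's ENC.

The scored codon set excludes the three stop codons and the single-codon
amino acids Met (ATG) and Trp (TGG), leaving 59 informative codons in 18
synonymous families. RSCU_ij = n_i * g_ij / sum_j g_ij where g_ij is the
count of codon j in family i and n_i the family size; the effective number
of codons follows Wright's estimator

    F_i = (n * sum p_hat^2 - 1) / (n - 1)        per family with n >= 2
    ENC  = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6

with class means taken over usable families and Wright's repair for a
missing three-fold class (F3 := (F2 + F4)/2).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .genetic_code import FAMILY_SIZE, SCORED_CODONS, SYN_FAMILIES, to_rna
from .seq_io import CodingSequence, CubkitError

ENC_MIN, ENC_MAX = 20.0, 61.0

RscuClass = Literal["over", "under", "neutral", "undefined"]


@dataclass(frozen=True)
class CodonCounts:
    """Counts over the 59 informative codons for one sequence or pooled group."""

    counts: Mapping[str, int]
    scope: str = ""

    def __post_init__(self) -> None:
        extra = set(self.counts) - set(SCORED_CODONS)
        if extra:
            raise CubkitError(f"non-scored codons in counts: {sorted(extra)}")

    def family_total(self, aa: str) -> int:
        return sum(self.counts.get(c, 0) for c in SYN_FAMILIES[aa])


def count_codons(
    seqs: CodingSequence | Sequence[CodingSequence],
    pooling: Literal["per_sequence", "pooled"] = "per_sequence",
    scope: str = "",
) -> CodonCounts | list[CodonCounts]:
    """Count scored codons; stops never appear in validated CDSs, Met/Trp
    are skipped."""
    if isinstance(seqs, CodingSequence):
        seqs = [seqs]
        if pooling == "per_sequence":
            return _count_one(seqs[0])
    if pooling == "pooled":
        total: Counter = Counter()
        for s in seqs:
            total.update(_count_one(s).counts)
        return CodonCounts(counts=dict(total), scope=scope or "pooled")
    return [_count_one(s) for s in seqs]


def _count_one(s: CodingSequence) -> CodonCounts:
    c = Counter(cod for cod in s.codons if cod in set(SCORED_CODONS))
    return CodonCounts(counts=dict(c), scope=s.id)


@dataclass(frozen=True)
class RSCUTable:
    """RSCU value and representation class per scored codon.

    Families with zero observations have RSCU ``nan`` and class
    ``undefined`` — never 0, which would mean active avoidance.
    """

    values: Mapping[str, float]
    classes: Mapping[str, RscuClass]
    scope: str = ""
    undefined_families: tuple[str, ...] = ()

    def as_frame(self, rna: bool = True) -> pd.DataFrame:
        rows = []
        for codon in SCORED_CODONS:
            rows.append(
                {
                    "codon": to_rna(codon) if rna else codon,
                    "amino_acid": next(
                        aa for aa, cods in SYN_FAMILIES.items() if codon in cods
                    ),
                    "rscu": self.values[codon],
                    "class": self.classes[codon],
                }
            )
        return pd.DataFrame(rows)


def rscu(counts: CodonCounts, hi: float = 1.6, lo: float = 0.6) -> RSCUTable:
    """RSCU per codon with representation classes.

    Thresholds are strict on both sides: RSCU > ``hi`` is over-represented,
    < ``lo`` under-represented, anything else (including the boundaries)
    neutral.
    """
    values: dict[str, float] = {}
    classes: dict[str, RscuClass] = {}
    undefined: list[str] = []
    for aa, codons in SYN_FAMILIES.items():
        total = sum(counts.counts.get(c, 0) for c in codons)
        if total == 0:
            undefined.append(aa)
            for c in codons:
                values[c] = float("nan")
                classes[c] = "undefined"
            continue
        n_i = FAMILY_SIZE[aa]
        for c in codons:
            v = n_i * counts.counts.get(c, 0) / total
            values[c] = v
            classes[c] = classify_value(v, hi=hi, lo=lo)
    return RSCUTable(
        values=values,
        classes=classes,
        scope=counts.scope,
        undefined_families=tuple(sorted(undefined)),
    )


def classify_value(v: float, hi: float = 1.6, lo: float = 0.6) -> RscuClass:
    """Representation class of one RSCU value (strict inequalities)."""
    if np.isnan(v):
        return "undefined"
    if v > hi:
        return "over"
    if v < lo:
        return "under"
    return "neutral"


def classify_rscu(table: RSCUTable, hi: float = 1.6, lo: float = 0.6) -> dict[str, RscuClass]:
    """Re-derive representation classes from an RSCU table (e.g. with
    non-default thresholds)."""
    return {c: classify_value(v, hi=hi, lo=lo) for c, v in table.values.items()}


def group_rscu(
    seqs: Sequence[CodingSequence],
    group_by: Sequence[str] = ("host", "region"),
    hi: float = 1.6,
    lo: float = 0.6,
) -> pd.DataFrame:
    """One pooled RSCU column per group (codon counts summed, then RSCU).

    This is the heatmap matrix treatment: one value per group cell, not a
    mean of per-sequence RSCUs. Returns a 59-row frame, codons RNA-spelled,
    one column per group label.
    """
    df = pd.DataFrame(
        [{"idx": i, **{k: getattr(s, k) for k in group_by}} for i, s in enumerate(seqs)]
    )
    out = None
    for key, grp in df.groupby(list(group_by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        label = "|".join(str(k) for k in key)
        pooled = count_codons([seqs[i] for i in grp["idx"]], pooling="pooled", scope=label)
        tab = rscu(pooled, hi=hi, lo=lo).as_frame(rna=True)
        if out is None:
            out = tab[["codon", "amino_acid"]].copy()
        out[label] = tab["rscu"].to_numpy()
    if out is None:
        raise CubkitError("no groups to summarize")
    return out


@dataclass(frozen=True)
class ENCValue:
    """Wright's effective number of codons with per-class diagnostics.

    ``enc`` is ``nan`` when undefined. ``f_means`` maps degeneracy class
    (2, 3, 4, 6) to the mean codon homozygosity of usable families;
    ``repaired`` lists classes filled in by Wright's conventions,
    ``clamped`` is set when a sampling excursion above 61 was clipped.
    """

    enc: float
    f_means: Mapping[int, float] = field(default_factory=dict)
    repaired: tuple[int, ...] = ()
    clamped: bool = False
    scope: str = ""

    @property
    def defined(self) -> bool:
        return not np.isnan(self.enc)


#: how many amino-acid families each degeneracy class contributes to ENC
CLASS_WEIGHTS = {2: 9, 3: 1, 4: 5, 6: 3}


def enc(counts: CodonCounts) -> ENCValue:
    """Wright's ENC from scored codon counts.

    Families with fewer than 2 observations are excluded from their class
    mean. A missing three-fold class mean is repaired as (F2+F4)/2; any
    other missing or zero class mean makes the ENC undefined (returned as
    ``nan``) rather than infinite. Values above 61 (finite-sample
    excursions) are clamped and flagged.
    """
    per_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in SYN_FAMILIES.items():
        obs = np.array([counts.counts.get(c, 0) for c in codons], dtype=float)
        n = obs.sum()
        if n <= 1:
            continue
        p = obs / n
        f = (n * float(np.sum(p**2)) - 1.0) / (n - 1.0)
        per_class[FAMILY_SIZE[aa]].append(f)

    f_means: dict[int, float] = {
        k: float(np.mean(v)) for k, v in per_class.items() if v
    }
    repaired: list[int] = []
    if 3 not in f_means and 2 in f_means and 4 in f_means:
        f_means[3] = (f_means[2] + f_means[4]) / 2.0
        repaired.append(3)
    usable = all(k in f_means and f_means[k] > 0 for k in CLASS_WEIGHTS)
    if not usable:
        return ENCValue(
            enc=float("nan"), f_means=f_means, repaired=tuple(repaired),
            scope=counts.scope,
        )
    value = 2.0 + sum(w / f_means[k] for k, w in CLASS_WEIGHTS.items())
    clamped = value > ENC_MAX
    value = min(value, ENC_MAX)
    return ENCValue(
        enc=value, f_means=f_means, repaired=tuple(repaired),
        clamped=clamped, scope=counts.scope,
    )


def enc_table(seqs: Iterable[CodingSequence]) -> pd.DataFrame:
    """Per-sequence ENC values with labels."""
    rows = []
    for s in seqs:
        e = enc(count_codons(s))
        rows.append(
            {"id": s.id, "host": s.host, "region": s.region,
             "enc": e.enc, "defined": e.defined}
        )
    return pd.DataFrame(rows)


def group_enc(
    seqs: Sequence[CodingSequence],
    group_by: Sequence[str] = ("host", "region"),
) -> pd.DataFrame:
    """Unweighted per-group mean of per-sequence ENC values.

    A group containing any undefined member is flagged; its mean is taken
    over the defined members only.
    """
    tab = enc_table(seqs)
    rows = []
    for key, grp in tab.groupby(
        [tab[k] if k in tab.columns else k for k in group_by], sort=True
    ):
        key = key if isinstance(key, tuple) else (key,)
        defined = grp.loc[grp["defined"], "enc"]
        rows.append(
            {
                **dict(zip(group_by, key)),
                "mean_enc": float(defined.mean()) if len(defined) else float("nan"),
                "n": len(grp),
                "n_undefined": int((~grp["defined"]).sum()),
                "flagged": bool((~grp["defined"]).any()),
            }
        )
    return pd.DataFrame(rows)
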