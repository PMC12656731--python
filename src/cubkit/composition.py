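"""Nucleotide and positional composition, dinucleotide odds, codon-pair bias.

Composition percentages are reported on the 0–100 scale the field plots
(GC3%, A3% …); the force-analysis module consumes the same quantities as
[0, 1] proportions. Dinucleotide relative abundance follows the classical
odds-ratio definition rho_xy = f_xy / (f_x * f_y), and codon-pair bias the
amino-acid-conditioned log-odds codon pair score with the analyzed corpus
itself as the reference.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, fields
from itertools import product
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .genetic_code import BASES, CODON_TO_AA, STOP_CODONS
from .seq_io import CodingSequence, CubkitError

DINUCLEOTIDES = tuple("".join(p) for p in product(BASES, repeat=2))

FramePolicy = Literal["all", "p1p2", "p2p3", "p3p1"]


@dataclass(frozen=True)
class CompositionProfile:
    """Per-sequence composition, percentages on the 0–100 scale.

    ``u`` / ``u3`` report thymine content under its RNA spelling, matching
    how plant-virus codon studies tabulate composition. ``gc12`` is the
    arithmetic mean of ``gc1`` and ``gc2``.
    """

    a: float
    c: float
    g: float
    u: float
    au: float
    gc: float
    a3: float
    c3: float
    g3: float
    u3: float
    gc1: float
    gc2: float
    gc3: float
    gc12: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def composition_profile(cds: CodingSequence) -> CompositionProfile:
    """Nucleotide composition of one validated CDS.

    Overall percentages are over the full (stop-trimmed) CDS; positional
    metrics are over codon positions 1, 2 and 3 respectively.
    """
    seq = cds.seq
    if not seq:
        raise CubkitError(f"{cds.id}: empty sequence")
    n = len(seq)
    tot = Counter(seq)
    p1 = Counter(seq[0::3])
    p2 = Counter(seq[1::3])
    p3 = Counter(seq[2::3])
    nc = n / 3

    def pct(counter: Counter, bases: str, denom: float) -> float:
        return 100.0 * sum(counter[b] for b in bases) / denom

    gc1 = pct(p1, "GC", nc)
    gc2 = pct(p2, "GC", nc)
    return CompositionProfile(
        a=pct(tot, "A", n),
        c=pct(tot, "C", n),
        g=pct(tot, "G", n),
        u=pct(tot, "T", n),
        au=pct(tot, "AT", n),
        gc=pct(tot, "GC", n),
        a3=pct(p3, "A", nc),
        c3=pct(p3, "C", nc),
        g3=pct(p3, "G", nc),
        u3=pct(p3, "T", nc),
        gc1=gc1,
        gc2=gc2,
        gc3=pct(p3, "GC", nc),
        gc12=(gc1 + gc2) / 2.0,
    )


def profile_table(seqs: Iterable[CodingSequence]) -> pd.DataFrame:
    """Per-sequence composition profiles as a tidy table."""
    rows = []
    for s in seqs:
        row = {"id": s.id, "host": s.host, "region": s.region}
        row.update(composition_profile(s).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def group_composition(
    seqs: Sequence[CodingSequence],
    group_by: Sequence[str] = ("host", "region"),
) -> pd.DataFrame:
    """Per-group mean and sample SD (n−1) of every composition field.

    Groups of size 1 are reported with SD 0 and ``singleton=True`` so the
    reader knows the spread is unestimable, not absent.
    """
    tab = profile_table(seqs)
    if tab.empty:
        raise CubkitError("no sequences to summarize")
    metric_cols = [f.name for f in fields(CompositionProfile)]
    out_rows = []
    for key, grp in tab.groupby(list(group_by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        n = len(grp)
        for m in metric_cols:
            vals = grp[m].to_numpy(dtype=float)
            out_rows.append(
                {
                    **dict(zip(group_by, key)),
                    "metric": m,
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if n > 1 else 0.0,
                    "n": n,
                    "singleton": n == 1,
                }
            )
    return pd.DataFrame(out_rows)


def dinucleotide_odds(
    cds: CodingSequence | str,
    frame_policy: FramePolicy = "all",
) -> pd.DataFrame:
    """Dinucleotide relative abundance rho_xy = f_xy / (f_x f_y).

    ``frame_policy`` selects which overlapping dinucleotide start sites are
    counted: every position (default, the compseq-style whole-CDS count) or
    only codon positions 1–2, 2–3, or the 3–1 bridge between consecutive
    codons. Mononucleotide frequencies always come from the same sequence.
    Returns a 16-row table with observed/expected frequencies, rho and a
    ``defined`` flag (False where f_x * f_y = 0).
    """
    seq = cds.seq if isinstance(cds, CodingSequence) else cds
    if len(seq) < 2:
        raise CubkitError("sequence shorter than 2 nt")
    starts: range
    if frame_policy == "all":
        starts = range(len(seq) - 1)
    elif frame_policy == "p1p2":
        starts = range(0, len(seq) - 1, 3)
    elif frame_policy == "p2p3":
        starts = range(1, len(seq) - 1, 3)
    elif frame_policy == "p3p1":
        starts = range(2, len(seq) - 1, 3)
    else:
        raise ValueError(f"unknown frame_policy {frame_policy!r}")
    pair_counts = Counter(seq[i : i + 2] for i in starts)
    n_pairs = sum(pair_counts.values())
    if n_pairs == 0:
        raise CubkitError("no dinucleotide sites under this frame policy")
    mono = Counter(seq)
    n = len(seq)
    rows = []
    for d in DINUCLEOTIDES:
        f_obs = pair_counts[d] / n_pairs
        f_exp = (mono[d[0]] / n) * (mono[d[1]] / n)
        defined = f_exp > 0
        rows.append(
            {
                "dinucleotide": d,
                "observed": pair_counts[d],
                "f_obs": f_obs,
                "f_exp": f_exp,
                "rho": f_obs / f_exp if defined else float("nan"),
                "defined": defined,
            }
        )
    return pd.DataFrame(rows)


def corpus_dinucleotide_odds(
    seqs: Sequence[CodingSequence], frame_policy: FramePolicy = "all"
) -> pd.DataFrame:
    """Dinucleotide odds of a corpus: counts pooled across sequences.

    Pairs never span record boundaries.
    """
    pair = Counter()
    mono = Counter()
    n_pairs = 0
    n = 0
    for s in seqs:
        tab = dinucleotide_odds(s, frame_policy)
        pair.update(dict(zip(tab["dinucleotide"], tab["observed"])))
        mono.update(s.seq)
        n_pairs += int(tab["observed"].sum())
        n += len(s.seq)
    rows = []
    for d in DINUCLEOTIDES:
        f_obs = pair[d] / n_pairs
        f_exp = (mono[d[0]] / n) * (mono[d[1]] / n)
        defined = f_exp > 0
        rows.append(
            {
                "dinucleotide": d,
                "observed": pair[d],
                "f_obs": f_obs,
                "f_exp": f_exp,
                "rho": f_obs / f_exp if defined else float("nan"),
                "defined": defined,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CodonPairStats:
    """Codon pair scores for a corpus scored against its own usage.

    ``pair_table`` has one row per *observed* ordered codon pair with its
    CPS; ``per_sequence`` holds each sequence's CPB (unweighted mean CPS of
    its consecutive codon pairs); ``cpb`` is the unweighted mean over
    sequences. Pairs whose expected count is zero are flagged and excluded,
    with the exclusion count reported.
    """

    pair_table: pd.DataFrame
    per_sequence: pd.DataFrame
    cpb: float
    n_excluded_pairs: int


def _pair_iter(seq: str):
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for a, b in zip(codons, codons[1:]):
        yield a, b


def codon_pair_bias(corpus: Sequence[CodingSequence]) -> CodonPairStats:
    """Codon pair score and bias of a corpus against its own usage.

    CPS(AB) = ln[ F(AB)·F(aa_A)·F(aa_B) / (F(A)·F(B)·F(aa_A aa_B)) ] with
    all F terms being raw counts over the corpus (the count scale cancels
    in the ratio). Consecutive pairs are counted within sequences only.
    Stop codons never occur in validated CDSs; Met and Trp codons *are*
    included, as codon-pair statistics condition on the encoded amino
    acids rather than on synonymous families.
    """
    if not corpus:
        raise CubkitError("empty corpus")
    codon_count: Counter = Counter()
    aa_count: Counter = Counter()
    pair_count: Counter = Counter()
    aapair_count: Counter = Counter()
    for s in corpus:
        for c in s.codons:
            if c in STOP_CODONS:
                raise CubkitError(f"{s.id}: stop codon in validated CDS")
            codon_count[c] += 1
            aa_count[CODON_TO_AA[c]] += 1
        for a, b in _pair_iter(s.seq):
            pair_count[(a, b)] += 1
            aapair_count[(CODON_TO_AA[a], CODON_TO_AA[b])] += 1

    cps: dict[tuple[str, str], float] = {}
    n_excluded = 0
    rows = []
    for (a, b), obs in sorted(pair_count.items()):
        aa_a, aa_b = CODON_TO_AA[a], CODON_TO_AA[b]
        denom = codon_count[a] * codon_count[b] * aapair_count[(aa_a, aa_b)]
        numer = obs * aa_count[aa_a] * aa_count[aa_b]
        expected = (
            codon_count[a]
            * codon_count[b]
            * aapair_count[(aa_a, aa_b)]
            / (aa_count[aa_a] * aa_count[aa_b])
        )
        if denom == 0 or expected == 0:
            n_excluded += 1
            rows.append(
                {"codon_a": a, "codon_b": b, "observed": obs,
                 "expected": expected, "cps": float("nan"), "defined": False}
            )
            continue
        score = math.log(numer / denom)
        cps[(a, b)] = score
        rows.append(
            {"codon_a": a, "codon_b": b, "observed": obs,
             "expected": expected, "cps": score, "defined": True}
        )

    seq_rows = []
    for s in corpus:
        scores = [cps[(a, b)] for a, b in _pair_iter(s.seq) if (a, b) in cps]
        seq_rows.append(
            {
                "id": s.id,
                "host": s.host,
                "region": s.region,
                "n_pairs": max(len(s.codons) - 1, 0),
                "cpb": float(np.mean(scores)) if scores else float("nan"),
            }
        )
    per_seq = pd.DataFrame(seq_rows)
    corpus_cpb = float(per_seq["cpb"].mean())
    return CodonPairStats(
        pair_table=pd.DataFrame(rows),
        per_sequence=per_seq,
        cpb=corpus_cpb,
        n_excluded_pairs=n_excluded,
    )
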