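"""Synthetic coding-sequence corpora with known ground truth.

The generator emulates the statistical structure that codon-usage analyses
assume in real viral data, so every pipeline stage has a parameter-recovery
test without downloads:

* ``selection`` regime: codons drawn from a fixed per-family preference
  table (identical for every sequence), the signature of translational
  selection — GC3 varies little between sequences and ENC falls below the
  mutation-only expectation as preferences sharpen.
* ``mutation`` regime: every nucleotide of a sequence drawn i.i.d. under
  that sequence's own GC bias (Sueoka's mutation-equilibrium picture),
  with stop codons redrawn — GC12 tracks GC3 (neutrality slope near 1)
  and PR2 sits at (0.5, 0.5) because the bias is strand-symmetric.
* ``mixed`` interpolates the two codon distributions.

CpG suppression multiplies the probability of any codon choice that would
create a CG dinucleotide (inside the codon or across the junction with the
previous codon) by a factor in (0, 1], then renormalizes — emulating the
CpG avoidance seen in many plant and animal RNA viruses.

One seeded generator per corpus; per-sequence substreams are derived from
(seed, sequence index) so corpora are reproducible regardless of the order
sequences are realized in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genetic_code import CODON_TO_AA, SENSE_CODONS, SYN_FAMILIES
from .seq_io import CodingSequence, CubkitError, write_fasta

DEFAULT_HOST_SIZES: Mapping[str, int] = {"citrus": 18, "Actinidia": 26, "Malus": 2}
DEFAULT_REGIONS: tuple[str, ...] = ("polyprotein", "MP", "CP")

_CODON_ARRAY = np.array(SENSE_CODONS)
_N_CODONS = len(SENSE_CODONS)
_INTERNAL_CG = np.array([c.count("CG") for c in SENSE_CODONS])
_STARTS_G = np.array([c[0] == "G" for c in SENSE_CODONS])
_BASES = "ACGT"


@dataclass(frozen=True)
class GeneratorSpec:
    """Everything that determines a synthetic corpus.

    ``host_sizes`` × ``regions`` defines the pseudo-isolate layout
    (defaults: 18/26/2 isolates in three host groups, three coding regions
    each). ``codons_per_sequence`` may be a single int or one int per
    region. The preference table used by the selection regime is either
    given explicitly or drawn once per corpus from a symmetric Dirichlet
    with the given concentration (smaller concentration → sharper
    preferences → lower ENC).
    """

    codons_per_sequence: int | Mapping[str, int] = 500
    regime: str = "selection"  # selection | mutation | mixed
    aa_composition: Mapping[str, float] | None = None
    preference: Mapping[str, Mapping[str, float]] | None = None
    dirichlet_concentration: float | None = 1.0
    gc_bias_range: tuple[float, float] = (0.3, 0.7)
    mix_weight: float = 0.5
    cpg_factor: float = 1.0
    host_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_HOST_SIZES)
    )
    regions: tuple[str, ...] = DEFAULT_REGIONS
    seed: int = 0

    def n_isolates(self) -> int:
        return sum(self.host_sizes.values())

    def region_length(self, region: str) -> int:
        if isinstance(self.codons_per_sequence, int):
            return self.codons_per_sequence
        return self.codons_per_sequence[region]


def uniform_aa_composition() -> dict[str, float]:
    """Uniform over the 18 scored amino acids (no Met/Trp)."""
    aas = sorted(SYN_FAMILIES)
    return {aa: 1.0 / len(aas) for aa in aas}


def au_rich_preferences(strength: float = 1.0) -> dict[str, dict[str, float]]:
    """A/U-ending codon preference preset, the composition bias typical of
    flexivirus coding sequences; ``strength`` scales the log-odds per A/T."""
    pref: dict[str, dict[str, float]] = {}
    for aa, codons in SYN_FAMILIES.items():
        w = np.array([np.exp(strength * (c.count("A") + c.count("T"))) for c in codons])
        w = w / w.sum()
        pref[aa] = dict(zip(codons, w.tolist()))
    return pref


def _draw_preferences(spec: GeneratorSpec, rng: np.random.Generator) -> dict:
    if spec.preference is not None:
        pref = {}
        for aa, table in spec.preference.items():
            if aa not in SYN_FAMILIES:
                raise CubkitError(f"unknown amino acid {aa!r} in preference table")
            total = float(sum(table.values()))
            if total <= 0:
                raise CubkitError(f"amino acid {aa} has all-zero preferences")
            pref[aa] = {c: table.get(c, 0.0) / total for c in SYN_FAMILIES[aa]}
        for aa in SYN_FAMILIES:
            pref.setdefault(
                aa, {c: 1.0 / len(SYN_FAMILIES[aa]) for c in SYN_FAMILIES[aa]}
            )
        return pref
    conc = spec.dirichlet_concentration
    if conc is None:
        return {aa: {c: 1.0 / len(cs) for c in cs} for aa, cs in SYN_FAMILIES.items()}
    pref = {}
    for aa in sorted(SYN_FAMILIES):
        cs = SYN_FAMILIES[aa]
        p = rng.dirichlet(np.full(len(cs), conc))
        pref[aa] = dict(zip(cs, p.tolist()))
    return pref


def _selection_codon_probs(spec: GeneratorSpec, pref: Mapping) -> np.ndarray:
    aa_comp = dict(spec.aa_composition or uniform_aa_composition())
    total = sum(aa_comp.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        aa_comp = {aa: p / total for aa, p in aa_comp.items()}
    q = np.zeros(_N_CODONS)
    for i, codon in enumerate(SENSE_CODONS):
        aa = CODON_TO_AA[codon]
        if aa in SYN_FAMILIES:
            q[i] = aa_comp.get(aa, 0.0) * pref[aa][codon]
        else:  # Met / Trp only if explicitly requested in aa_composition
            q[i] = aa_comp.get(aa, 0.0)
    if q.sum() <= 0:
        raise CubkitError("selection regime: all codon probabilities zero")
    return q / q.sum()


def _mutation_codon_probs(gc: float) -> np.ndarray:
    p = {"G": gc / 2.0, "C": gc / 2.0, "A": (1.0 - gc) / 2.0, "T": (1.0 - gc) / 2.0}
    q = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in SENSE_CODONS])
    return q / q.sum()  # stop-codon mass redistributed = per-codon redraw


def _draw_codon_indices(
    q: np.ndarray, n: int, cpg_factor: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` codon indices from ``q`` with CpG thinning.

    With no suppression the draw is i.i.d.; otherwise codon choice becomes
    a Markov chain on the previous codon's last base, because codons
    starting with G are thinned after a codon ending in C.
    """
    if cpg_factor == 1.0:
        return rng.choice(_N_CODONS, size=n, p=q)
    base = q * cpg_factor**_INTERNAL_CG
    # one adjusted distribution per previous final base (only C differs)
    after_c = base * np.where(_STARTS_G, cpg_factor, 1.0)
    cdf_plain = np.cumsum(base / base.sum())
    cdf_after_c = np.cumsum(after_c / after_c.sum())
    u = rng.random(n)
    out = np.empty(n, dtype=np.int64)
    prev_c = False
    for i in range(n):
        cdf = cdf_after_c if prev_c else cdf_plain
        idx = int(np.searchsorted(cdf, u[i], side="right"))
        out[i] = min(idx, _N_CODONS - 1)
        prev_c = SENSE_CODONS[idx][2] == "C"
    return out


def generate_corpus(spec: GeneratorSpec) -> tuple[list[CodingSequence], dict]:
    """Generate the corpus defined by ``spec`` plus its true-parameter record.

    One CDS per pseudo-isolate per region; sequences are in-frame, contain
    no stop codons, and the returned dict records the regime, the realized
    preference table, each sequence's mutational GC bias (mutation/mixed
    regimes) and the seed.
    """
    if spec.regime not in ("selection", "mutation", "mixed"):
        raise CubkitError(f"unknown regime {spec.regime!r}")
    lo, hi = spec.gc_bias_range
    if not (0.0 < lo <= hi < 1.0):
        raise CubkitError(f"infeasible gc_bias_range {spec.gc_bias_range}")
    if not 0.0 < spec.cpg_factor <= 1.0:
        raise CubkitError(f"cpg_factor must be in (0, 1], got {spec.cpg_factor}")

    master = np.random.default_rng([spec.seed, 0])
    pref = _draw_preferences(spec, master)
    q_sel = (
        _selection_codon_probs(spec, pref)
        if spec.regime in ("selection", "mixed")
        else None
    )

    seqs: list[CodingSequence] = []
    gc_biases: dict[str, float] = {}
    counter = 0
    for host in spec.host_sizes:
        for k in range(spec.host_sizes[host]):
            iso = f"{host}_{k + 1:03d}"
            counter += 1
            for r_idx, region in enumerate(spec.regions):
                counter_rng = np.random.default_rng([spec.seed, counter, r_idx + 1])
                n_cod = spec.region_length(region)
                if spec.regime == "selection":
                    q = q_sel
                else:
                    gc = counter_rng.uniform(lo, hi)
                    gc_biases[f"{iso}|{region}"] = float(gc)
                    q_mut = _mutation_codon_probs(gc)
                    q = (
                        q_mut
                        if spec.regime == "mutation"
                        else (1 - spec.mix_weight) * q_sel + spec.mix_weight * q_mut
                    )
                idx = _draw_codon_indices(q, n_cod, spec.cpg_factor, counter_rng)
                seq = "".join(_CODON_ARRAY[idx])
                seqs.append(
                    CodingSequence(
                        id=iso, seq=seq, accession=f"SYN{counter:05d}",
                        host=host, region=region,
                    )
                )
    params = {
        "seed": spec.seed,
        "regime": spec.regime,
        "cpg_factor": spec.cpg_factor,
        "preference": {aa: pref[aa] for aa in sorted(pref)}
        if spec.regime in ("selection", "mixed")
        else None,
        "gc_bias": gc_biases or None,
        "n_sequences": len(seqs),
        "codons_per_sequence": spec.codons_per_sequence
        if isinstance(spec.codons_per_sequence, int)
        else dict(spec.codons_per_sequence),
    }
    return seqs, params


def make_fixture_metadata(spec: GeneratorSpec) -> pd.DataFrame:
    """Isolate metadata matching :func:`generate_corpus` ids.

    Default layout: 18/26/2 isolates across three pseudo-hosts, all
    non-recombinant, with the three region labels available per isolate.
    """
    rows = []
    counter = 0
    for host in spec.host_sizes:
        for k in range(spec.host_sizes[host]):
            counter += 1
            rows.append(
                {
                    "id": f"{host}_{k + 1:03d}",
                    "accession": f"SYN{counter:05d}",
                    "host": host,
                    "regions": ";".join(spec.regions),
                    "recombinant": False,
                }
            )
    return pd.DataFrame(rows)


def synthetic_host_table(
    name: str, seed: int, sharpness: float = 1.0
) -> "pd.Series[float]":
    """A synthetic Kazusa-style per-thousand usage table for a pseudo-host.

    Per-family codon preferences are Dirichlet(1/sharpness) draws; returns
    a 64-entry per-thousand series (stops get a small fixed share).
    """
    import zlib

    from .genetic_code import ALL_CODONS, STOP_CODONS

    rng = np.random.default_rng([seed, zlib.crc32(name.encode()) % (2**31)])
    weights = {}
    for aa in sorted(SYN_FAMILIES):
        cs = SYN_FAMILIES[aa]
        p = rng.dirichlet(np.full(len(cs), 1.0 / sharpness))
        for c, v in zip(cs, p):
            weights[c] = float(v) * 50.0
    for c in ALL_CODONS:
        if c not in weights:
            weights[c] = 1.0 if c not in STOP_CODONS else 0.5
    total = sum(weights.values())
    return pd.Series(
        {c: 1000.0 * weights[c] / total for c in ALL_CODONS}, name=name
    )


def write_demo_bundle(out_dir: str | Path, spec: GeneratorSpec) -> dict[str, Path]:
    """Emit a complete analyzable input bundle: per-region FASTA files,
    a metadata TSV, two synthetic host tables and the true-parameter JSON.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seqs, params = generate_corpus(spec)
    paths: dict[str, Path] = {}
    for region in spec.regions:
        sub = [s for s in seqs if s.region == region]
        paths[f"fasta_{region}"] = write_fasta(sub, out_dir / f"{region}.fasta")
    meta = make_fixture_metadata(spec)
    meta_path = out_dir / "metadata.tsv"
    meta.to_csv(meta_path, sep="\t", index=False)
    paths["metadata"] = meta_path
    for i, host in enumerate(("hostA", "hostB")):
        tab = synthetic_host_table(host, seed=spec.seed + 1000 + i)
        p = out_dir / f"host_{host}.tsv"
        tab.rename_axis("codon").reset_index(name="weight").to_csv(
            p, sep="\t", index=False
        )
        paths[f"host_{host}"] = p
    params_path = out_dir / "true_params.json"
    params_path.write_text(json.dumps(params, indent=2, sort_keys=True))
    paths["true_params"] = params_path
    return paths
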