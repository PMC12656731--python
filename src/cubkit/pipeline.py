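"""Full-analysis orchestration: composition → RSCU/ENC → force plots → CAI.

:func:`run_all` executes every stage over a validated, metadata-joined
corpus and writes the complete TSV report set plus a machine-readable run
manifest. Stage failures abort with a stage-named error rather than
leaving a partial bundle behind.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .seq_io import (
    CodingSequence,
    CubkitError,
    HostCodonUsageTable,
    filter_nonrecombinant,
    join_metadata,
    read_fasta,
    read_host_table,
    read_metadata,
    validate_cds,
    write_report,
)
from .composition import (
    corpus_dinucleotide_odds,
    codon_pair_bias,
    group_composition,
    profile_table,
)
from .codon_metrics import enc_table, group_enc, group_rscu
from .force_analysis import (
    enc_plot,
    expected_enc_curve,
    neutrality,
    neutrality_table,
    pr2_table,
)
from .host_adaptation import cai_table, host_ranking

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every configurable decision of a pipeline run.

    The config is serialized verbatim into the run manifest so any output
    table can be traced back to the exact settings that produced it.
    """

    fasta_by_region: Mapping[str, str | Path] = field(default_factory=dict)
    metadata_path: str | Path | None = None
    host_table_paths: Mapping[str, str | Path] = field(default_factory=dict)
    out_dir: str | Path = "cubkit_out"
    group_by: tuple[str, ...] = ("host", "region")
    rscu_hi: float = 1.6
    rscu_lo: float = 0.6
    pr2_site_policy: str = "fourfold"
    cai_floor: float = 0.01
    ambiguity_policy: str = "drop_ambiguous"
    exclude_recombinant: bool = True
    float_decimals: int = 4
    seed: int | None = None  # demo mode only


def load_inputs(
    config: RunConfig,
) -> tuple[list[CodingSequence], list[HostCodonUsageTable]]:
    """Read, validate and label the input corpus described by ``config``."""
    if not config.fasta_by_region:
        raise CubkitError("stage=input: no FASTA inputs configured")
    meta = None
    if config.metadata_path is not None:
        meta = read_metadata(config.metadata_path)
        if config.exclude_recombinant:
            n_before = len(meta)
            meta = filter_nonrecombinant(meta)
            logger.info(
                "recombinant filter: retained %d of %d isolates", len(meta), n_before
            )
    seqs: list[CodingSequence] = []
    for region, path in config.fasta_by_region.items():
        raw = read_fasta(path)
        validated = [
            validate_cds(r, policy=config.ambiguity_policy) for r in raw
        ]
        if meta is not None:
            keep = set(meta["id"])
            validated = [s for s in validated if s.id in keep]
            validated = join_metadata(validated, meta)
        from dataclasses import replace

        seqs.extend(replace(s, region=region) for s in validated)
    if not seqs:
        raise CubkitError("stage=input: no sequences after filtering/validation")
    host_tables = [
        read_host_table(path, host=name)
        for name, path in sorted(config.host_table_paths.items())
    ]
    return seqs, host_tables


def run_all(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis and write the report bundle.

    Emits, per grouping: composition mean±SD, pooled RSCU matrix, ENC
    tables, ENC-plot points and null curve, neutrality fits with force
    partition, PR2 points, dinucleotide and codon-pair tables, CAI
    summaries and host ranking (when host tables are given), plus a JSON
    run manifest.
    """
    seqs, host_tables = load_inputs(config)
    group_by = tuple(config.group_by)
    grouped = all(
        getattr(s, k) is not None for s in seqs for k in group_by
    )
    if not grouped:
        raise CubkitError(
            "stage=grouping: grouped analysis requested but sequences lack labels"
        )

    tables: dict[str, pd.DataFrame] = {}

    def stage(name: str, fn):
        try:
            return fn()
        except CubkitError:
            raise
        except Exception as exc:  # surface the failing stage, no partial output
            raise CubkitError(f"stage={name}: {exc}") from exc

    tables["composition_per_sequence"] = stage("composition", lambda: profile_table(seqs))
    tables["composition_by_group"] = stage(
        "composition", lambda: group_composition(seqs, group_by)
    )
    tables["rscu_matrix"] = stage(
        "rscu",
        lambda: group_rscu(seqs, group_by, hi=config.rscu_hi, lo=config.rscu_lo),
    )
    tables["enc_per_sequence"] = stage("enc", lambda: enc_table(seqs))
    tables["enc_by_group"] = stage("enc", lambda: group_enc(seqs, group_by))
    tables["enc_plot_points"] = stage("encplot", lambda: enc_plot(seqs))
    tables["enc_plot_curve"] = stage("encplot", expected_enc_curve)
    tables["pr2_points"] = stage(
        "pr2", lambda: pr2_table(seqs, site_policy=config.pr2_site_policy)
    )
    tables["neutrality_by_group"] = stage(
        "neutrality", lambda: neutrality_table(neutrality(seqs, group_by=("region",)))
    )
    tables["dinucleotide_odds"] = stage(
        "dinuc", lambda: corpus_dinucleotide_odds(seqs)
    )
    cp = stage("cpb", lambda: codon_pair_bias(seqs))
    tables["codon_pair_scores"] = cp.pair_table
    tables["cpb_per_sequence"] = cp.per_sequence
    if host_tables:
        tables["cai_per_sequence"] = stage(
            "cai", lambda: cai_table(seqs, host_tables, floor=config.cai_floor)
        )
        summary, ranking = stage(
            "cai", lambda: host_ranking(seqs, host_tables, floor=config.cai_floor)
        )
        tables["cai_by_host_region"] = summary
        tables["cai_host_ranking"] = ranking

    out_dir = Path(config.out_dir)
    written = write_report(tables, out_dir, float_decimals=config.float_decimals)
    manifest = {
        "tool": "cubkit",
        "version": __version__,
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in _jsonable(asdict(config)).items()
        },
        "n_sequences": len(seqs),
        "corpus_cpb": cp.cpb,
        "formulas": {
            "rscu": "n_i*g_ij/sum_j(g_ij); strict thresholds "
            f"over>{config.rscu_hi}, under<{config.rscu_lo}",
            "enc": "Wright: 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6; "
            "F=(n*sum p^2 - 1)/(n-1); missing F3 repaired as (F2+F4)/2",
            "expected_enc": "2 + s + 29/(s^2 + (1-s)^2)",
            "cps": "ln[F(AB)*F(aaA)*F(aaB)/(F(A)*F(B)*F(aaA aaB))], "
            "reference = analyzed corpus",
            "cai": f"exp(mean log w), Sharp-Li w, zero-usage floor {config.cai_floor}",
            "neutrality": "OLS GC12~GC3; mutation_pct=|slope|*100",
            "pr2_site_policy": config.pr2_site_policy,
            "group_sd": "sample SD (n-1)",
        },
        "tables": [p.name for p in written],
    }
    manifest_path = out_dir / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {**{p.stem: p for p in written}, "run_manifest": manifest_path}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def bundled_isolate_metadata() -> pd.DataFrame:
    """The packaged 56-isolate screening fixture (10 recombinant records
    with published hosts/accessions; 46 synthetic non-recombinant rows
    with the documented 18/26/2 host partition)."""
    from importlib.resources import files

    path = files("cubkit.data").joinpath("clbv_isolates.tsv")
    with path.open() as fh:  # type: ignore[attr-defined]
        return read_metadata(fh)
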