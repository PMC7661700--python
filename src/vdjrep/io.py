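"""File interchange: FASTA, AIRR-style rearrangement TSV, truth tables,
run manifests.

The rearrangement TSV follows the AIRR community schema where a concept
maps cleanly (``sequence_id``, ``sequence``, ``v_call``, ``d_call``,
``j_call``, ``junction``, ``junction_aa``, ``cdr3``, ``cdr3_aa``,
``productive``); package-specific extensions (junction insert strings,
mutation records, region lengths, donor/cell bookkeeping) are plain extra
columns, so external repertoire tools can still consume the core fields.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from vdjrep import __version__
from vdjrep.annotator import AnnotatedRearrangement, AnnotationFailure, MutationRecord
from vdjrep.simulator import SimulatedRepertoire, SimulationConfig

AIRR_COLUMNS = [
    "sequence_id", "sequence", "v_call", "d_call", "j_call",
    "junction", "junction_aa", "cdr3", "cdr3_aa", "productive",
    # extensions
    "n1", "n2", "nonfunctional_reason", "mutation_frequency",
    "mutated_status", "v_score", "j_score", "cdr3_start", "cdr3_end",
    "mutation_records", "region_lengths", "flags", "donor_id", "cell_id",
]

_REGIONS = ("FR2", "CDR2", "FR3", "CDR3", "FR4")


class SchemaError(ValueError):
    pass


def write_fasta(records, path: str | Path) -> None:
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list:
    return list(SeqIO.parse(str(path), "fasta"))


def _encode_mutation_records(mutations: Sequence[MutationRecord]) -> str:
    return ";".join(
        f"{m.position}:{m.germline_base}>{m.observed_base}:{m.region}:"
        f"{int(m.in_hotspot)}"
        for m in mutations
    )


def _decode_mutation_records(text: str) -> list[MutationRecord]:
    if not text:
        return []
    out = []
    for item in text.split(";"):
        pos, change, region, hot = item.split(":")
        old, new = change.split(">")
        out.append(MutationRecord(int(pos), old, new, region, bool(int(hot))))
    return out


def annotations_to_frame(
    annotations: Sequence[AnnotatedRearrangement],
) -> pd.DataFrame:
    rows = []
    for a in annotations:
        junction = junction_aa = ""
        if a.cdr3_start >= 3 and a.cdr3_end + 3 <= len(a.sequence):
            junction = a.sequence[a.cdr3_start - 3: a.cdr3_end + 3]
            if a.cdr3_aa:
                from Bio.Seq import Seq
                junction_aa = str(Seq(junction).translate())
        rows.append({
            "sequence_id": a.sequence_id,
            "sequence": a.sequence,
            "v_call": a.v_call,
            "d_call": a.d_call,
            "j_call": a.j_call,
            "junction": junction,
            "junction_aa": junction_aa,
            "cdr3": a.cdr3_nt,
            "cdr3_aa": a.cdr3_aa,
            "productive": "T" if a.productive else "F",
            "n1": a.n1_seq,
            "n2": a.n2_seq,
            "nonfunctional_reason": a.nonfunctional_reason,
            "mutation_frequency": round(a.mutation_frequency, 4),
            "mutated_status": "T" if a.mutated_status else "F",
            "v_score": a.v_score,
            "j_score": a.j_score,
            "cdr3_start": a.cdr3_start,
            "cdr3_end": a.cdr3_end,
            "mutation_records": _encode_mutation_records(a.mutations),
            "region_lengths": ";".join(
                f"{r}={a.region_lengths.get(r, 0)}" for r in _REGIONS
            ),
            "flags": ",".join(a.flags),
            "donor_id": a.donor_id,
            "cell_id": a.cell_id,
        })
    return pd.DataFrame(rows, columns=AIRR_COLUMNS)


def write_annotations(
    annotations: Sequence[AnnotatedRearrangement], path: str | Path
) -> None:
    annotations_to_frame(annotations).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> list[AnnotatedRearrangement]:
    """Read a rearrangement TSV back into annotation objects."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(AIRR_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"rearrangement TSV missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        region_lengths = {}
        for item in row["region_lengths"].split(";"):
            if item:
                k, v = item.split("=")
                region_lengths[k] = int(v)
        start, end = int(row["cdr3_start"]), int(row["cdr3_end"])
        out.append(AnnotatedRearrangement(
            sequence_id=row["sequence_id"],
            sequence=row["sequence"],
            v_call=row["v_call"],
            d_call=row["d_call"],
            j_call=row["j_call"],
            v_score=float(row["v_score"]),
            j_score=float(row["j_score"]),
            n1_seq=row["n1"],
            n2_seq=row["n2"],
            cdr3_nt=row["cdr3"],
            cdr3_aa=row["cdr3_aa"],
            cdr3_start=start,
            cdr3_end=end,
            productive=row["productive"] == "T",
            nonfunctional_reason=row["nonfunctional_reason"],
            mutations=_decode_mutation_records(row["mutation_records"]),
            mutation_frequency=float(row["mutation_frequency"]),
            mutated_status=row["mutated_status"] == "T",
            region_lengths=region_lengths,
            flags=tuple(f for f in row["flags"].split(",") if f),
            donor_id=row["donor_id"],
            cell_id=row["cell_id"],
        ))
    return out


def write_failures(failures: Sequence[AnnotationFailure], path: str | Path) -> None:
    pd.DataFrame(
        [{"sequence_id": f.sequence_id, "reason": f.reason} for f in failures],
        columns=["sequence_id", "reason"],
    ).to_csv(path, sep="\t", index=False)


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"donor_id": str, "cell_id": str,
                               "sequence_id": str, "clone_id": str},
        keep_default_na=False,
        converters={"n1_seq": str, "n2_seq": str, "mutations": str},
    )


def config_to_yaml(config: SimulationConfig) -> str:
    data = dataclasses.asdict(config)
    data["colonies_per_cell"] = list(config.colonies_per_cell)
    data["patterns_per_cell_dist"] = list(config.patterns_per_cell_dist)
    data["shm_rate_dist"] = [list(t) for t in config.shm_rate_dist]
    return yaml.safe_dump(data, sort_keys=True)


def config_from_yaml(text: str) -> SimulationConfig:
    data = yaml.safe_load(text)
    data["colonies_per_cell"] = tuple(data["colonies_per_cell"])
    data["patterns_per_cell_dist"] = tuple(data["patterns_per_cell_dist"])
    data["shm_rate_dist"] = tuple(tuple(t) for t in data["shm_rate_dist"])
    return SimulationConfig(**data)


def config_hash(config: SimulationConfig) -> str:
    return hashlib.sha256(config_to_yaml(config).encode()).hexdigest()[:16]


def write_manifest(path: str | Path, command: str, **fields) -> None:
    manifest = {"tool": "vdjrep", "version": __version__, "command": command}
    manifest.update(fields)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def write_repertoire(rep: SimulatedRepertoire, out_dir: str | Path) -> dict[str, str]:
    """Write a simulated repertoire (FASTA + truth TSV + config + manifest)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": str(out / "repertoire.fasta"),
        "truth": str(out / "truth.tsv"),
        "config": str(out / "config.yaml"),
        "manifest": str(out / "manifest.json"),
    }
    write_fasta(rep.records, paths["fasta"])
    write_truth(rep.truth, paths["truth"])
    Path(paths["config"]).write_text(config_to_yaml(rep.config))
    write_manifest(
        paths["manifest"], "simulate",
        seed=rep.config.seed, preset=rep.config.preset,
        config_hash=config_hash(rep.config),
        n_sequences=len(rep.records),
        outputs={k: v for k, v in paths.items() if k != "manifest"},
    )
    return paths
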