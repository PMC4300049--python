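"""Readers and writers: FASTA peptides, fragment TSV/FASTA, reports, manifests."""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import yaml
from Bio import SeqIO

from .assembly import AssemblyProtocol, Fragment
from .optimizer import EAConfig
from .thermo import NNParameterSet

__all__ = [
    "read_peptide_fasta",
    "read_fragments_tsv",
    "write_fragments_tsv",
    "write_fragments_fasta",
    "read_fragments_fasta",
    "protocol_report",
    "write_protocol_json",
    "load_config",
    "run_manifest",
]


def read_peptide_fasta(path) -> tuple[str, str]:
    """(record id, peptide) from a single-record FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"{path}: expected exactly one FASTA record, found {len(records)}"
        )
    rec = records[0]
    return rec.id, str(rec.seq).upper()


def write_fragments_tsv(fragments, path, tubes=None) -> None:
    tube_of = {}
    if tubes is not None:
        for t, names in enumerate(tubes):
            for n in names:
                tube_of[n] = t
    with open(path, "w") as fh:
        fh.write("name\trole\tsequence\tphosphorylated\ttube\n")
        for f in fragments:
            fh.write(
                f"{f.name}\t{f.role}\t{f.sequence}\t"
                f"{'true' if f.phosphorylated else 'false'}\t"
                f"{tube_of.get(f.name, 0)}\n"
            )


def read_fragments_tsv(path) -> list[Fragment]:
    import csv

    fragments = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, 2):
            try:
                fragments.append(
                    Fragment(
                        row["name"],
                        row["sequence"].upper(),
                        row["role"],
                        row.get("phosphorylated", "false").lower() == "true",
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return fragments


def write_fragments_fasta(fragments, path) -> None:
    """FASTA with role/phosphorylation carried in the description line."""
    with open(path, "w") as fh:
        for f in fragments:
            phos = "phosphorylated" if f.phosphorylated else "unphosphorylated"
            fh.write(f">{f.name} role={f.role} {phos}\n{f.sequence}\n")


def read_fragments_fasta(path) -> list[Fragment]:
    fragments = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        role = "helper" if "role=helper" in desc else "main"
        phos = "unphosphorylated" not in desc and (
            "phosphorylated" in desc or role == "main"
        )
        fragments.append(Fragment(rec.id, str(rec.seq).upper(), role, phos))
    return fragments


def protocol_report(protocol: AssemblyProtocol, fragments) -> dict:
    """JSON-ready summary of a planned assembly."""
    tube_of = {}
    for t, names in enumerate(protocol.tubes):
        for n in names:
            tube_of[n] = t
    return {
        "verdict": protocol.report.verdict,
        "S": protocol.S,
        "feasible": protocol.feasible,
        "n_tubes": len(protocol.tubes),
        "tubes": [list(t) for t in protocol.tubes],
        "threshold_tm": protocol.report.threshold,
        "fragments": [
            {
                "name": f.name,
                "role": f.role,
                "sequence": f.sequence,
                "phosphorylated": f.phosphorylated,
                "tube": tube_of.get(f.name, 0),
            }
            for f in fragments
        ],
        "events": [
            {"pair": list(pair), "tm": tm} for pair, tm in protocol.events
        ],
        "conflicts": [
            {"pair": list(pair), "reason": reason}
            for pair, reason in protocol.conflicts
        ],
    }


def write_protocol_json(protocol, fragments, path) -> None:
    Path(path).write_text(json.dumps(protocol_report(protocol, fragments), indent=2))


def load_config(path) -> EAConfig:
    """EAConfig from a YAML or JSON mapping (unknown keys rejected)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    valid = set(EAConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {', '.join(sorted(unknown))}")
    return EAConfig(**data)


def run_manifest(config, seed: int, params: NNParameterSet) -> dict:
    """Reproducibility manifest: config echo, seed, parameter checksum."""
    from . import __version__

    cfg = asdict(config) if is_dataclass(config) else dict(config)
    return {
        "software": "lcrgene",
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "nn_params": {"name": params.name, "sha256": params.checksum},
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
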