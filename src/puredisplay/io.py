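"""Format readers/writers and run manifests shared by the CLI.

FASTA via Biopython (tolerant of wrapped lines and mixed case; sequences
are upper-cased on read), tables via pandas (comma-separated, UTF-8,
mandatory header), schemes and scenarios as YAML, manifests and summaries
as JSON.  Manifests record the seed, the input paths with content hashes,
and the package version, so a run can be reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .library_design import CdrFrequencyTable, CdrScheme, LibraryScheme
from .panning_sim import CloneClass, ClonePopulation, PanningConfig
from .synthetic_data import Scenario

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_cdr_table",
    "write_cdr_table",
    "scheme_to_dict",
    "scheme_from_dict",
    "save_scheme",
    "load_scheme",
    "save_scenario",
    "load_scenario",
    "write_manifest",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(name, upper-cased sequence) pairs from a FASTA file."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seq_records, str(path), "fasta")


def read_cdr_table(path: str | Path, cdr_id: str | None = None) -> CdrFrequencyTable:
    """TSV with columns position, residue, frequency (optional cdr column)."""
    frame = pd.read_csv(path, sep="\t")
    required = {"position", "residue", "frequency"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"CDR table {path} missing columns {sorted(missing)}")
    if cdr_id is None:
        cdr_id = str(frame["cdr"].iloc[0]) if "cdr" in frame.columns else Path(path).stem
    freqs: list[dict[str, float]] = []
    for pos, group in frame.groupby("position", sort=True):
        freqs.append(dict(zip(group["residue"], group["frequency"].astype(float))))
    return CdrFrequencyTable(cdr_id=cdr_id, freqs=tuple(freqs))


def write_cdr_table(path: str | Path, table: CdrFrequencyTable) -> None:
    rows = [
        {"cdr": table.cdr_id, "position": pos + 1, "residue": res, "frequency": f}
        for pos, dist in enumerate(table.freqs)
        for res, f in sorted(dist.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def scheme_to_dict(scheme: LibraryScheme) -> dict:
    return {
        "framework": list(scheme.framework),
        "cdrs": [
            {
                "cdr_id": c.cdr_id,
                "length": c.length,
                "fixed": {int(k): v for k, v in sorted(c.fixed.items())},
                "alphabet": c.alphabet,
            }
            for c in scheme.cdrs
        ],
        "codon_table": dict(sorted(scheme.codon_table.items())),
    }


def scheme_from_dict(data: Mapping) -> LibraryScheme:
    cdrs = tuple(
        CdrScheme(
            cdr_id=c["cdr_id"],
            length=int(c["length"]),
            fixed={int(k): v for k, v in c.get("fixed", {}).items()},
            alphabet=c.get("alphabet", ""),
        )
        for c in data["cdrs"]
    )
    return LibraryScheme(
        framework=tuple(data["framework"]),
        cdrs=cdrs,
        codon_table=dict(data["codon_table"]),
    )


def save_scheme(path: str | Path, scheme: LibraryScheme) -> None:
    Path(path).write_text(yaml.safe_dump(scheme_to_dict(scheme), sort_keys=False))


def load_scheme(path: str | Path) -> LibraryScheme:
    return scheme_from_dict(yaml.safe_load(Path(path).read_text()))


def save_scenario(path: str | Path, scenario: Scenario) -> None:
    pop = scenario.population
    data = {
        "name": scenario.name,
        "classes": {
            cid: {"retention": c.retention, "capture": dict(c.capture)}
            for cid, c in sorted(pop.classes.items())
        },
        "population": [
            {
                "id": pop.ids[i],
                "class_id": pop.class_ids[i],
                "count": float(pop.counts[i]),
                "spike": bool(pop.spike[i]),
            }
            for i in range(len(pop.ids))
        ],
        "rounds": [
            {
                "display_efficiency": cfg.display_efficiency,
                "incubation_release": cfg.incubation_release,
                "surface": cfg.surface,
                "preincubation_depletion": cfg.preincubation_depletion,
                "washes": cfg.washes,
                "elution": cfg.elution,
                "amplification_factor": cfg.amplification_factor,
                "mutation_rate": cfg.mutation_rate,
            }
            for cfg in scenario.configs
        ],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_scenario(path: str | Path) -> Scenario:
    data = yaml.safe_load(Path(path).read_text())
    classes = {
        cid: CloneClass(class_id=cid, retention=spec["retention"], capture=spec["capture"])
        for cid, spec in data["classes"].items()
    }
    entries = data["population"]
    counts = np.asarray([e["count"] for e in entries])
    if np.all(counts == np.round(counts)):
        counts = counts.astype(np.int64)
    pop = ClonePopulation(
        ids=tuple(e["id"] for e in entries),
        class_ids=tuple(e["class_id"] for e in entries),
        counts=counts,
        spike=np.asarray([bool(e.get("spike", False)) for e in entries], dtype=bool),
        classes=classes,
    )
    configs = [PanningConfig(**r) for r in data["rounds"]]
    return Scenario(name=data.get("name", Path(path).stem), configs=configs, population=pop)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    outdir: str | Path,
    subcommand: str,
    seed: int | None,
    inputs: Sequence[str | Path] = (),
    config: Mapping | None = None,
) -> Path:
    """Write ``manifest.json`` recording inputs, config hash, seed, version.

    Deliberately timestamp-free so identical runs produce identical files.
    """
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = dict(config or {})
    config_blob = json.dumps(config, sort_keys=True)
    manifest = {
        "subcommand": subcommand,
        "seed": seed,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
        "config": config,
        "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
        "version": __version__,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
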