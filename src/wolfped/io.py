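"""Readers and writers for the pipeline's file formats.

All tables are UTF-8 CSV (comma) for data and TSV (tab) for reports,
with explicit headers; dates are ISO-8601; coordinates are carried
verbatim in whatever CRS the metadata declares.  Write-then-read is
the identity for every format here.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .error_model import ErrorRates
from .genodata import (
    AlleleFrequencyTable,
    IndividualRecord,
    ReplicateObservation,
    SampleRecord,
    as_genotype,
)
from .pedigree_core import Pedigree
from .protocol import CorrectionEntry, CorrectionsLedger, ProtocolConfig
from .pedigree_mcmc import Priors

__all__ = [
    "read_genotype_table",
    "write_genotype_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_frequency_table",
    "write_frequency_table",
    "read_individuals",
    "write_individuals",
    "read_pedigree",
    "write_pedigree",
    "read_error_rates",
    "write_error_rates",
    "read_corrections",
    "write_corrections",
    "load_config",
    "save_config",
    "RunManifest",
    "write_manifest",
]

GENOTYPE_HEADER = ["sample_id", "locus", "replicate", "allele1", "allele2"]


class InputError(ValueError):
    """Malformed or inconsistent input file."""


def read_genotype_table(path: str | Path) -> list[ReplicateObservation]:
    """Long-format replicate genotype CSV -> observations.

    Header sample_id,locus,replicate,allele1,allele2; empty allele
    cells mean a failed replicate.  Duplicate (sample, locus,
    replicate) keys are an error naming the offenders.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != GENOTYPE_HEADER:
        raise InputError(
            f"{path}: expected header {','.join(GENOTYPE_HEADER)}, got {','.join(df.columns)}"
        )
    try:
        reps = df["replicate"].astype(int)
    except ValueError as e:
        raise InputError(f"{path}: non-numeric replicate index ({e})") from None
    keys = list(zip(df["sample_id"], df["locus"], reps))
    seen: set = set()
    dups = []
    for k in keys:
        if k in seen:
            dups.append(k)
        seen.add(k)
    if dups:
        raise InputError(f"{path}: duplicate replicate keys: {dups[:10]}")
    out = []
    for (sid, loc, rep), a1, a2 in zip(keys, df["allele1"], df["allele2"]):
        out.append(ReplicateObservation(sid, loc, rep, as_genotype(a1 or None, a2 or None)))
    return out


def write_genotype_table(obs: Iterable[ReplicateObservation], path: str | Path) -> None:
    rows = []
    for r in obs:
        a1, a2 = ("", "") if r.allele_pair is None else r.allele_pair
        rows.append(
            {"sample_id": r.sample_id, "locus": r.locus_id, "replicate": r.replicate_index,
             "allele1": a1, "allele2": a2}
        )
    pd.DataFrame(rows, columns=GENOTYPE_HEADER).to_csv(path, index=False)


SAMPLE_HEADER = ["sample_id", "date", "x", "y", "source_class", "collector", "species_flag"]


def read_sample_metadata(path: str | Path) -> list[SampleRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != SAMPLE_HEADER:
        raise InputError(f"{path}: expected header {','.join(SAMPLE_HEADER)}")
    out = []
    for row in df.itertuples(index=False):
        try:
            d = date.fromisoformat(row.date)
        except ValueError:
            raise InputError(f"{path}: unparseable date {row.date!r} for {row.sample_id}") from None
        out.append(
            SampleRecord(row.sample_id, d, float(row.x), float(row.y),
                         row.source_class, row.collector, row.species_flag)
        )
    return out


def write_sample_metadata(samples: Iterable[SampleRecord], path: str | Path) -> None:
    rows = [
        {"sample_id": s.sample_id, "date": s.date.isoformat(), "x": repr(s.x), "y": repr(s.y),
         "source_class": s.source_class, "collector": s.collector, "species_flag": s.species_flag}
        for s in samples
    ]
    pd.DataFrame(rows, columns=SAMPLE_HEADER).to_csv(path, index=False)


def read_frequency_table(path: str | Path) -> AlleleFrequencyTable:
    df = pd.read_csv(path, dtype={"locus": str, "allele": str, "frequency": float})
    if list(df.columns) != ["locus", "allele", "frequency"]:
        raise InputError(f"{path}: expected header locus,allele,frequency")
    return AlleleFrequencyTable.from_frame(df)


def write_frequency_table(freqs: AlleleFrequencyTable, path: str | Path) -> None:
    df = freqs.to_frame()
    df["frequency"] = df["frequency"].map(repr)
    df.to_csv(path, index=False)


def write_individuals(
    individuals: Sequence[IndividualRecord], loci: Sequence[str], path: str | Path
) -> None:
    """Individuals CSV: metadata columns then one column pair per locus."""
    rows = []
    for ind in individuals:
        row: dict = {
            "individual_id": ind.individual_id,
            "sex": ind.sex,
            "n_samples": len(ind.sample_ids),
            "first_seen": ind.first_seen.isoformat() if ind.first_seen else "",
            "last_seen": ind.last_seen.isoformat() if ind.last_seen else "",
            "loci_typed": ind.n_loci_typed,
        }
        for loc in loci:
            g = ind.genotype.get(loc)
            row[f"{loc}_1"], row[f"{loc}_2"] = ("", "") if g is None else g
        rows.append(row)
    cols = ["individual_id", "sex", "n_samples", "first_seen", "last_seen", "loci_typed"]
    cols += [f"{loc}_{i}" for loc in loci for i in (1, 2)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_individuals(path: str | Path) -> list[IndividualRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    meta = {"individual_id", "sex", "n_samples", "first_seen", "last_seen", "loci_typed"}
    loci = sorted({c[:-2] for c in df.columns if c not in meta and c.endswith(("_1", "_2"))})
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        geno = {
            loc: as_genotype(d[f"{loc}_1"] or None, d[f"{loc}_2"] or None) for loc in loci
        }
        out.append(
            IndividualRecord(
                individual_id=d["individual_id"],
                genotype=geno,
                sex=d["sex"],
                first_seen=date.fromisoformat(d["first_seen"]) if d["first_seen"] else None,
                last_seen=date.fromisoformat(d["last_seen"]) if d["last_seen"] else None,
            )
        )
    return out


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    """Pedigree TSV: id, dam, sire, dam_prob, sire_prob (lossless)."""
    pedigree.to_frame().to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path, sexes: Mapping[str, str] | None = None) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "dam": str, "sire": str})
    return Pedigree.from_frame(df, sexes)


def write_error_rates(rates: ErrorRates, path: str | Path) -> None:
    rates.to_frame().to_csv(path, index=False)


def read_error_rates(path: str | Path, default_e1: float = 0.04, default_e2: float = 0.022) -> ErrorRates:
    return ErrorRates.from_frame(pd.read_csv(path), default_e1, default_e2)


CORRECTIONS_HEADER = ["offspring", "field", "old_value", "new_value", "reason", "note"]


def read_corrections(path: str | Path) -> CorrectionsLedger:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != CORRECTIONS_HEADER:
        raise InputError(f"{path}: expected header {','.join(CORRECTIONS_HEADER)}")
    ledger = CorrectionsLedger()
    for row in df.itertuples(index=False):
        ledger.add(row.offspring, row.field, row.old_value, row.new_value, row.reason, row.note)
    return ledger


def write_corrections(ledger: CorrectionsLedger, path: str | Path) -> None:
    rows = [asdict(e) for e in ledger.entries]
    pd.DataFrame(rows, columns=CORRECTIONS_HEADER).to_csv(path, index=False)


def save_config(config: ProtocolConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_config(path: str | Path) -> ProtocolConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    priors = d.pop("priors", None)
    kwargs = dict(d)
    if "medium_band" in kwargs and kwargs["medium_band"] is not None:
        kwargs["medium_band"] = tuple(kwargs["medium_band"])
    cfg = ProtocolConfig(**kwargs)
    if priors:
        for k in ("e1_beta", "e2_beta"):
            if k in priors:
                priors[k] = tuple(priors[k])
        cfg.priors = Priors(**priors)
    return cfg


@dataclass
class RunManifest:
    """Provenance record written next to every pipeline output."""

    tool: str = "wolfped"
    version: str = "0.1.0"
    command: str = ""
    seeds: dict[str, int] = field(default_factory=dict)
    config_hash: str = ""
    input_hashes: dict[str, str] = field(default_factory=dict)
    started: str = ""
    finished: str = ""
    counts: dict[str, int] = field(default_factory=dict)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def write_manifest(
    out_dir: str | Path,
    command: str,
    seeds: Mapping[str, int],
    inputs: Iterable[str | Path] = (),
    config: ProtocolConfig | None = None,
    counts: Mapping[str, int] | None = None,
    started: datetime | None = None,
) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    m = RunManifest(
        command=command,
        seeds=dict(seeds),
        config_hash=(
            hashlib.sha256(json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()[:16]
            if config
            else ""
        ),
        input_hashes={str(p): _hash_file(Path(p)) for p in inputs if Path(p).exists()},
        started=(started or datetime.now()).isoformat(timespec="seconds"),
        finished=datetime.now().isoformat(timespec="seconds"),
        counts=dict(counts or {}),
    )
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(asdict(m), indent=2) + "\n")
    return path
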