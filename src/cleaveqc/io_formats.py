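"""Input/output for the pipeline's tabular and sequence formats, plus run configuration.

No science lives here: parsing, validation and round-trippable table writing only.
Coordinates are 1-based inclusive on the protein; ``-`` is the sentinel flanking
residue at a protein terminus (the convention of common search-engine exports).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 canonical amino-acid one-letter codes.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity / non-canonical codes rejected by default.
NONCANONICAL_RESIDUES = frozenset("BJOUXZ")


class FormatError(ValueError):
    """Raised on malformed input files or schema violations."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein database entry: accession plus uppercase amino-acid sequence."""

    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"protein {self.accession!r} has an empty sequence")

    def residue(self, position: int) -> str:
        """Residue at 1-based ``position``."""
        return self.sequence[position - 1]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Modification:
    """A localized modification on a peptide.

    ``position`` is 1-based within the peptide (0 denotes the peptide N-terminus,
    as used for protein N-terminal acetylation). ``localization_score`` is the
    site-confidence score exported by the search engine (e.g. A-score), if any.
    """

    position: int
    name: str
    delta_mass: float
    localization_score: Optional[float] = None


@dataclass
class PeptideObservation:
    """One observed peptide feature mapped onto a protein."""

    sample_id: str
    peptide: str
    protein_accession: str
    start: int
    end: int
    preceding_residue: str
    following_residue: str
    modifications: list[Modification] = field(default_factory=list)
    intensity: float = 0.0
    reporter_intensities: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"peptide {self.peptide!r}: start {self.start} > end {self.end}"
            )
        if self.intensity < 0:
            raise FormatError(f"peptide {self.peptide!r}: negative intensity")


@dataclass
class RunConfig:
    """Run-level parameters shared across the pipeline.

    ``protease_classes`` is an *ordered* mapping from class name to P1-residue
    set; attribution of a nontryptic event goes to the first class containing
    its P1 residue. The defaults mirror the specificities of the neutrophil
    serine proteases: ELANE/PRTN3 cleave after Ala/Ile/Val (not Leu), CTSG
    after Trp/Leu/Phe/Tyr.
    """

    tryptic_residues: frozenset[str] = frozenset("KR")
    proline_blocks_cleavage: bool = False
    max_missed_cleavages: int = 4
    protease_classes: dict[str, frozenset[str]] = field(
        default_factory=lambda: {
            "ELANE_PRTN3": frozenset("AIV"),
            "CTSG": frozenset("WLFY"),
        }
    )
    dixon_alpha: float = 0.05
    trim_percentiles: tuple[float, float] = (5.0, 95.0)
    reference_channel_ids: list[str] = field(default_factory=list)
    seed: int = 20240112
    # behaviour switches
    strict_nontryptic: bool = False  # require both termini nontryptic for the category
    on_noncanonical: str = "error"  # or "skip"
    delimiter: str = "\t"

    def __post_init__(self) -> None:
        lo, hi = self.trim_percentiles
        if not (0.0 < lo < hi < 100.0):
            raise FormatError(
                f"trim_percentiles must be strictly increasing within (0,100); got {self.trim_percentiles}"
            )
        self.tryptic_residues = frozenset(self.tryptic_residues)
        self.protease_classes = {
            k: frozenset(v) for k, v in self.protease_classes.items()
        }

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tryptic_residues"] = sorted(self.tryptic_residues)
        d["protease_classes"] = {
            k: sorted(v) for k, v in self.protease_classes.items()
        }
        d["trim_percentiles"] = list(self.trim_percentiles)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "trim_percentiles" in d:
            d["trim_percentiles"] = tuple(d["trim_percentiles"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict())
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, on_noncanonical: str = "error") -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    The accession is the header token before the first whitespace. Sequences
    are uppercased and a single terminal ``*`` (stop) is stripped. Duplicate
    accessions and non-canonical residues (per ``on_noncanonical``) are errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        acc = rec.id
        if acc in seen:
            raise FormatError(f"duplicate accession in FASTA: {acc}")
        bad = set(seq) - CANONICAL_RESIDUES
        if bad:
            if on_noncanonical == "skip":
                logger.warning("skipping %s: non-canonical residues %s", acc, sorted(bad))
                continue
            raise FormatError(
                f"protein {acc} contains non-canonical residues: {sorted(bad)}"
            )
        seen.add(acc)
        records.append(ProteinRecord(acc, seq))
    if not records:
        raise FormatError(f"no FASTA records read from {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.accession}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PSM / feature tables
# ---------------------------------------------------------------------------

PSM_REQUIRED_COLUMNS = (
    "sample_id",
    "peptide",
    "protein_accession",
    "start",
    "end",
    "preceding_residue",
    "following_residue",
    "intensity",
)
PSM_OPTIONAL_COLUMNS = ("modifications",)


@dataclass
class ReadStats:
    """Row accounting for a table read; dropped + kept == n_rows always."""

    n_rows: int = 0
    n_kept: int = 0
    n_dropped_zero_intensity: int = 0


def parse_modifications(cell: str) -> list[Modification]:
    """Parse a ``pos:name:delta[:score]`` semicolon-separated modification cell."""
    if not cell or (isinstance(cell, float) and pd.isna(cell)):
        return []
    mods = []
    for token in str(cell).split(";"):
        token = token.strip()
        if not token:
            continue
        parts = token.split(":")
        if len(parts) not in (3, 4):
            raise FormatError(f"malformed modification token: {token!r}")
        score = float(parts[3]) if len(parts) == 4 and parts[3] != "" else None
        mods.append(Modification(int(parts[0]), parts[1], float(parts[2]), score))
    return mods


def format_modifications(mods: Sequence[Modification]) -> str:
    tokens = []
    for m in mods:
        t = f"{m.position}:{m.name}:{m.delta_mass:.10g}"
        if m.localization_score is not None:
            t += f":{m.localization_score:.10g}"
        tokens.append(t)
    return ";".join(tokens)


def parse_inline_modifications(annotated: str) -> tuple[str, list[Modification]]:
    """Normalize ``SEQ(+164.06)``-style inline notation into (sequence, triples).

    A parenthesized signed mass after residue *i* becomes a modification at
    peptide position *i* with an empty name; names in square brackets after the
    mass are kept (``S(+164.06)[DFP]``).
    """
    seq_chars: list[str] = []
    mods: list[Modification] = []
    i = 0
    while i < len(annotated):
        c = annotated[i]
        if c == "(":
            j = annotated.index(")", i)
            delta = float(annotated[i + 1 : j])
            name = ""
            i = j + 1
            if i < len(annotated) and annotated[i] == "[":
                j = annotated.index("]", i)
                name = annotated[i + 1 : j]
                i = j + 1
            mods.append(Modification(len(seq_chars), name, delta))
        else:
            seq_chars.append(c)
            i += 1
    return "".join(seq_chars), mods


def read_psm_table(
    path: str | Path, config: RunConfig
) -> tuple[list[PeptideObservation], ReadStats]:
    """Read a delimited PSM/feature table.

    Rows with intensity exactly zero are dropped and counted (a zero feature
    area means the peptide was not observed). Reporter-intensity columns are
    any columns named ``reporter_<channel>``.
    """
    df = pd.read_csv(path, sep=config.delimiter, dtype=str, keep_default_na=False)
    for col in PSM_REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing column: {col}")
    reporter_cols = [c for c in df.columns if c.startswith("reporter_")]
    stats = ReadStats(n_rows=len(df))
    observations: list[PeptideObservation] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        row = row._asdict()
        try:
            intensity = float(row["intensity"])
        except ValueError as exc:
            raise FormatError(
                f"non-numeric intensity {row['intensity']!r} at row {idx}"
            ) from exc
        if intensity == 0.0:
            stats.n_dropped_zero_intensity += 1
            continue
        reporters = None
        if reporter_cols:
            reporters = {
                c[len("reporter_") :]: float(row[c]) for c in reporter_cols if row[c] != ""
            }
        observations.append(
            PeptideObservation(
                sample_id=row["sample_id"],
                peptide=row["peptide"],
                protein_accession=row["protein_accession"],
                start=int(row["start"]),
                end=int(row["end"]),
                preceding_residue=row["preceding_residue"],
                following_residue=row["following_residue"],
                modifications=parse_modifications(row.get("modifications", "")),
                intensity=intensity,
                reporter_intensities=reporters,
            )
        )
    stats.n_kept = len(observations)
    logger.info(
        "read %d rows from %s: kept %d, dropped %d with zero intensity",
        stats.n_rows, path, stats.n_kept, stats.n_dropped_zero_intensity,
    )
    return observations, stats


def observations_to_frame(observations: Sequence[PeptideObservation]) -> pd.DataFrame:
    """Flatten observations into the canonical PSM-table schema."""
    rows = []
    for o in observations:
        row = {
            "sample_id": o.sample_id,
            "peptide": o.peptide,
            "protein_accession": o.protein_accession,
            "start": o.start,
            "end": o.end,
            "preceding_residue": o.preceding_residue,
            "following_residue": o.following_residue,
            "modifications": format_modifications(o.modifications),
            "intensity": o.intensity,
        }
        if o.reporter_intensities:
            for ch, v in o.reporter_intensities.items():
                row[f"reporter_{ch}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def write_table(records, path: str | Path, delimiter: str = "\t") -> None:
    """Write a homogeneous record collection as delimited text.

    Accepts a DataFrame, a list of dataclass instances, or a list of dicts.
    Column order is deterministic (first record's field order) and floats keep
    enough digits to round-trip within 1e-6 relative error.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if records and dataclasses.is_dataclass(records[0]):
            records = [dataclasses.asdict(r) for r in records]
        df = pd.DataFrame(records)
    df.to_csv(path, sep=delimiter, index=False, float_format="%.10g")


def read_table(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=delimiter)


def check_peptide_protein_consistency(
    observations: Sequence[PeptideObservation],
    proteins: Mapping[str, ProteinRecord],
) -> list[PeptideObservation]:
    """Return observations whose coordinates do not match the protein sequence.

    Violations are collected and reported, never silently dropped.
    """
    bad = []
    for o in observations:
        prot = proteins.get(o.protein_accession)
        if prot is None or prot.sequence[o.start - 1 : o.end] != o.peptide:
            bad.append(o)
    if bad:
        logger.warning("%d observations fail peptide/protein consistency", len(bad))
    return bad
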