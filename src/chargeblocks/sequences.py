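"""Sequence records, phosphosite tables and mutation specifications.

The central container is :class:`AnnotatedSequence`: an amino-acid string
together with a set of annotated phospho-accepting positions (1-based) and
the subset of those positions that are currently phosphorylated.  Keeping
the phospho *annotation* (where mitotic kinases act) separate from the
phospho *state* (whether the phosphate is attached) lets the same record
represent the interphase (dephosphorylated) and mitotic
(hyperphosphorylated) forms of a protein.

Positions are 1-based inclusive everywhere in the public API; conversion to
0-based indexing happens only inside numerical routines.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import SeqIO

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: letters accepted in permissive mode and mapped to X (charge 0)
AMBIGUOUS_RESIDUES = frozenset("BZJUO")

Direction = Literal["up", "down", "both"]


class SequenceError(ValueError):
    """Invalid sequence content or annotation."""


class FastaParseError(SequenceError):
    """Malformed FASTA input; the message names the offending line."""


class PhosphositeError(SequenceError):
    """Invalid phosphosite table or failed join against a sequence."""


@dataclass(frozen=True)
class AnnotatedSequence:
    """An amino-acid sequence with phosphosite annotations.

    Parameters
    ----------
    id
        Sequence identifier (for UniProt-derived input include an isoform
        tag, e.g. ``P46013-1``, so that position numbering is unambiguous).
    residues
        One-letter amino-acid string; canonical letters plus ``X``
        (unknown, carries charge 0).
    phosphosites
        1-based positions of annotated phospho-accepting residues.  Each
        must be S or T unless ``allow_non_st`` is set (then non-S/T sites
        are kept but contribute charge 0 when "phosphorylated").
    phosphorylated
        Subset of ``phosphosites`` currently carrying a phosphate.
    """

    id: str
    residues: str
    phosphosites: frozenset[int] = frozenset()
    phosphorylated: frozenset[int] = frozenset()
    description: str = ""
    allow_non_st: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - CANONICAL_RESIDUES - {"X"}
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains non-canonical letters "
                f"{sorted(bad)}; use read_fasta(..., permissive=True) to map "
                "ambiguity codes to X"
            )
        object.__setattr__(self, "phosphosites", frozenset(self.phosphosites))
        object.__setattr__(self, "phosphorylated", frozenset(self.phosphorylated))
        n = len(self.residues)
        for pos in self.phosphosites:
            if not 1 <= pos <= n:
                raise PhosphositeError(
                    f"phosphosite {pos} outside sequence {self.id!r} of length {n}"
                )
            res = self.residues[pos - 1]
            if res not in ("S", "T") and not self.allow_non_st:
                raise PhosphositeError(
                    f"phosphosite {pos} in {self.id!r} is {res}, not S/T "
                    "(pass allow_non_st=True to accept with charge 0)"
                )
        if not self.phosphorylated <= self.phosphosites:
            extra = sorted(self.phosphorylated - self.phosphosites)
            raise PhosphositeError(
                f"phosphorylated positions {extra} are not annotated phosphosites"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def residue_at(self, position: int) -> str:
        """One-letter residue at a 1-based position."""
        if not 1 <= position <= len(self.residues):
            raise SequenceError(
                f"position {position} outside sequence {self.id!r}"
            )
        return self.residues[position - 1]

    def is_phosphorylated(self, position: int) -> bool:
        return position in self.phosphorylated

    def replace(self, **changes) -> "AnnotatedSequence":
        return dataclasses.replace(self, **changes)

    def subsequence(self, start: int, end: int, id: str | None = None) -> "AnnotatedSequence":
        """Extract residues ``start..end`` (1-based inclusive), remapping
        phosphosite annotations into the new coordinate system."""
        if not (1 <= start <= end <= len(self.residues)):
            raise SequenceError(
                f"range {start}-{end} outside sequence {self.id!r} "
                f"of length {len(self.residues)}"
            )
        shift = start - 1
        keep = lambda s: frozenset(p - shift for p in s if start <= p <= end)
        return AnnotatedSequence(
            id=id if id is not None else f"{self.id}:{start}-{end}",
            residues=self.residues[start - 1 : end],
            phosphosites=keep(self.phosphosites),
            phosphorylated=keep(self.phosphorylated),
            description=self.description,
            allow_non_st=self.allow_non_st,
        )


def read_fasta(path: str | Path, permissive: bool = False) -> list[AnnotatedSequence]:
    """Read a FASTA file into :class:`AnnotatedSequence` records.

    Records come back in file order with empty phosphosite sets and the
    full description line retained.  In permissive mode, ambiguity codes
    (B, Z, J, U, O) are mapped to X; by default they are an error.
    """
    path = Path(path)
    # Light structural validation so errors can name the offending line;
    # the actual parsing is delegated to Bio.SeqIO.
    header_lines: list[int] = []
    body_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if header_lines and not body_seen:
                    raise FastaParseError(
                        f"{path}:{header_lines[-1]}: record has an empty sequence"
                    )
                if len(stripped) == 1:
                    raise FastaParseError(f"{path}:{lineno}: empty FASTA header")
                header_lines.append(lineno)
                body_seen = False
            else:
                if not header_lines:
                    raise FastaParseError(
                        f"{path}:{lineno}: sequence data before any '>' header"
                    )
                body_seen = True
    if not header_lines:
        raise FastaParseError(f"{path}: no FASTA records found")
    if not body_seen:
        raise FastaParseError(
            f"{path}:{header_lines[-1]}: record has an empty sequence"
        )

    records = []
    for rec, lineno in zip(SeqIO.parse(str(path), "fasta"), header_lines):
        residues = str(rec.seq).upper()
        bad = set(residues) - CANONICAL_RESIDUES - {"X"}
        if bad:
            if not permissive or not bad <= AMBIGUOUS_RESIDUES:
                raise FastaParseError(
                    f"{path}:{lineno}: record {rec.id!r} contains "
                    f"non-canonical letters {sorted(bad)}"
                )
            residues = "".join(
                "X" if c in AMBIGUOUS_RESIDUES else c for c in residues
            )
        records.append(
            AnnotatedSequence(id=rec.id, residues=residues, description=rec.description)
        )
    return records


def write_fasta(records: Iterable[AnnotatedSequence], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA (wrapped at ``width`` columns)."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description.startswith(rec.id) else rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


@dataclass(frozen=True)
class PhosphositeTable:
    """Table of (protein_id, position, residue, direction) phosphosite rows.

    ``direction`` records whether phosphorylation at the site increases
    ("up") or decreases ("down") upon mitotic entry.
    """

    frame: pd.DataFrame

    REQUIRED = ("protein_id", "position", "residue", "direction")
    DIRECTIONS = frozenset({"up", "down"})

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise PhosphositeError(f"phosphosite table missing columns {missing}")
        df = df.copy()
        df["position"] = df["position"].astype(int)
        df["protein_id"] = df["protein_id"].astype(str)
        df["residue"] = df["residue"].astype(str).str.upper()
        df["direction"] = df["direction"].astype(str).str.lower()
        unknown = sorted(set(df["direction"]) - self.DIRECTIONS)
        if unknown:
            raise PhosphositeError(
                f"unknown direction tokens {unknown}; expected one of "
                f"{sorted(self.DIRECTIONS)}"
            )
        dup = df.duplicated(subset=["protein_id", "position"], keep=False)
        if dup.any():
            pairs = df.loc[dup, ["protein_id", "position"]].drop_duplicates()
            raise PhosphositeError(
                "duplicate (protein, position) rows: "
                + ", ".join(f"{r.protein_id}:{r.position}" for r in pairs.itertuples())
            )
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.frame)

    def for_protein(self, protein_id: str, direction: Direction = "both") -> pd.DataFrame:
        df = self.frame[self.frame["protein_id"] == protein_id]
        if direction != "both":
            df = df[df["direction"] == direction]
        return df.reset_index(drop=True)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, int, str, str]]) -> "PhosphositeTable":
        return cls(pd.DataFrame(rows, columns=list(cls.REQUIRED)))


def read_phosphosites(path: str | Path) -> PhosphositeTable:
    """Read a tab- or comma-delimited phosphosite table with a header row."""
    df = pd.read_csv(path, sep=None, engine="python")
    return PhosphositeTable(df)


def write_phosphosites(table: PhosphositeTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def attach_sites(
    seq: AnnotatedSequence,
    table: PhosphositeTable,
    direction: Direction = "up",
) -> AnnotatedSequence:
    """Join a phosphosite table onto a sequence.

    Returns a copy of ``seq`` whose ``phosphosites`` are the table's
    positions for ``seq.id`` (filtered by mitotic ``direction``), all in the
    unmodified state.  The residue letter stated in each row must match the
    sequence at that position.
    """
    rows = table.for_protein(seq.id, direction)
    mismatches = []
    for row in rows.itertuples():
        if not 1 <= row.position <= len(seq):
            raise PhosphositeError(
                f"site {row.position} outside sequence {seq.id!r} "
                f"of length {len(seq)}"
            )
        actual = seq.residue_at(row.position)
        if actual != row.residue:
            mismatches.append(f"{row.position} (table {row.residue}, sequence {actual})")
    if mismatches:
        raise PhosphositeError(
            f"residue mismatches joining sites onto {seq.id!r}: "
            + "; ".join(mismatches)
        )
    return seq.replace(
        phosphosites=frozenset(rows["position"]), phosphorylated=frozenset()
    )


# ---------------------------------------------------------------------------
# mutation specifications

REGION_RULE_KINDS = ("neutral_to_E", "KR_to_Q", "ST_to_A", "ST_to_E")


@dataclass(frozen=True)
class PointRule:
    position: int
    from_residue: str
    to_residue: str


@dataclass(frozen=True)
class RegionRule:
    start: int
    end: int
    kind: str
    count: int | None = None  # number of substitutions for neutral_to_E

    def __post_init__(self) -> None:
        if self.kind not in REGION_RULE_KINDS:
            raise SequenceError(
                f"unknown region rule kind {self.kind!r}; "
                f"expected one of {REGION_RULE_KINDS}"
            )
        if self.start > self.end:
            raise SequenceError(f"region start {self.start} > end {self.end}")


@dataclass(frozen=True)
class MutationSpec:
    """An ordered, non-conflicting list of point and region rules."""

    rules: tuple[PointRule | RegionRule, ...]

    def validate_against(self, seq: AnnotatedSequence) -> None:
        touched: set[int] = set()
        for rule in self.rules:
            if isinstance(rule, PointRule):
                positions = {rule.position}
                if seq.residue_at(rule.position) != rule.from_residue:
                    raise SequenceError(
                        f"point rule at {rule.position}: sequence has "
                        f"{seq.residue_at(rule.position)}, rule expects {rule.from_residue}"
                    )
            else:
                if rule.end > len(seq):
                    raise SequenceError(
                        f"region {rule.start}-{rule.end} outside sequence of "
                        f"length {len(seq)}"
                    )
                positions = set(range(rule.start, rule.end + 1))
            overlap = touched & positions
            if overlap:
                raise SequenceError(
                    f"conflicting rules: positions {sorted(overlap)[:5]} touched twice"
                )
            touched |= positions


def read_mutation_spec(path: str | Path) -> MutationSpec:
    """Read a TSV of rules with columns kind, start, end, from, to, count.

    ``kind`` is ``point`` or one of the region rule kinds; ``from``/``to``
    apply to point rules, ``count`` to ``neutral_to_E`` regions.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    rules: list[PointRule | RegionRule] = []
    for _, row in df.iterrows():
        if row["kind"] == "point":
            rules.append(PointRule(int(row["start"]), row["from"], row["to"]))
        else:
            raw_count = str(row.get("count", "")).strip()
            count_val = int(raw_count) if raw_count else None
            rules.append(
                RegionRule(int(row["start"]), int(row["end"]), row["kind"], count_val)
            )
    return MutationSpec(tuple(rules))


# ---------------------------------------------------------------------------
# generic tabular reports

def write_report(records: Sequence, path: str | Path) -> None:
    """Write records (dataclasses, dicts or a DataFrame) as a TSV report.

    Column order is deterministic (insertion order of the record schema);
    floats are serialized with 6 significant digits; an empty record list
    yields a header-only file only when the schema is known (a DataFrame),
    otherwise an empty file with no rows.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = [
            dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
            for r in records
        ]
        df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
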