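"""Sex-annotated X-STR genotype tables.

X-chromosomal STR data are intrinsically sex-stratified: males are hemizygous
(one allele per locus), females diploid (an unordered pair).  Allele calls are
repeat-number labels, possibly with a microvariant suffix for partial repeats
("25.1" = 25 full repeats plus one extra base).  Labels are categories, not
measurements, so they are stored as exact integer pairs and never as floats.

Two tabular dialects are supported:

* ``slash-combined`` — one column per locus; female cells ``"10/25.1"``,
  male cells a single label.
* ``two-column`` — two adjacent columns per locus (the second empty or a
  duplicate of the first for males), the layout typing software exports.

The dialect is auto-detected from the header (duplicated locus names mean
two-column).  Missing calls are empty cells or ``NA``.
"""

from __future__ import annotations

import csv
import functools
import re
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "AlleleLabel",
    "Sample",
    "GenotypeTable",
    "GenotypeParseError",
    "HemizygosityError",
    "read_genotype_table",
    "write_genotype_table",
    "write_genepop",
]

_LABEL_RE = re.compile(r"^(\d+)(?:\.(\d))?$")
_MISSING_TOKENS = {"", "na", "nan", "none", "-", "."}

_SEX_CODES = {
    "m": "male", "male": "male",
    "f": "female", "female": "female",
}


class GenotypeParseError(ValueError):
    """Malformed genotype input (bad label, bad sex code, bad layout)."""


class HemizygosityError(GenotypeParseError):
    """A male carries two distinct alleles at an X-linked locus."""


@functools.total_ordering
@dataclass(frozen=True)
class AlleleLabel:
    """A repeat-number allele label, e.g. ``10`` or ``25.1``.

    ``integer_part`` is the full repeat count, ``microvariant`` the number of
    extra bases after the dot (0 when absent).
    """

    integer_part: int
    microvariant: int = 0

    def __post_init__(self) -> None:
        if self.integer_part < 0:
            raise GenotypeParseError(f"negative repeat count: {self.integer_part}")
        if not 0 <= self.microvariant <= 3:
            raise GenotypeParseError(
                f"microvariant suffix out of range: {self.microvariant}"
            )

    @classmethod
    def parse(cls, text: str) -> "AlleleLabel":
        m = _LABEL_RE.match(text.strip())
        if m is None:
            raise GenotypeParseError(f"malformed allele label: {text!r}")
        return cls(int(m.group(1)), int(m.group(2) or 0))

    def __str__(self) -> str:
        if self.microvariant:
            return f"{self.integer_part}.{self.microvariant}"
        return str(self.integer_part)

    def _key(self) -> tuple[int, int]:
        return (self.integer_part, self.microvariant)

    def __lt__(self, other: "AlleleLabel") -> bool:
        if not isinstance(other, AlleleLabel):
            return NotImplemented
        return self._key() < other._key()


@dataclass(frozen=True)
class Sample:
    sample_id: str
    sex: str  # "male" | "female"

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise GenotypeParseError(
                f"unknown sex code {self.sex!r} for sample {self.sample_id!r}"
            )


Call = tuple[AlleleLabel, ...]  # length 1 (male) or 2 (female, sorted)


@dataclass
class GenotypeTable:
    """Individuals x loci allele calls with sex annotation.

    ``calls[(sample_id, locus)]`` is a 1-tuple for males, a sorted 2-tuple for
    females, and absent for missing calls.  Locus order is preserved from
    input; duplicate sample ids are rejected.
    """

    samples: list[Sample]
    loci: list[str]
    calls: dict[tuple[str, str], Call] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise GenotypeParseError(f"duplicate sample ids: {dupes}")
        if len(set(self.loci)) != len(self.loci):
            raise GenotypeParseError("duplicate locus names")
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        by_id = {s.sample_id: s for s in self.samples}
        offenders = []
        for (sid, locus), call in self.calls.items():
            if sid not in by_id:
                raise GenotypeParseError(f"call for unknown sample {sid!r}")
            if locus not in self.loci:
                raise GenotypeParseError(f"call at unknown locus {locus!r}")
            sex = by_id[sid].sex
            if sex == "male":
                if len(call) == 2 and call[0] == call[1]:
                    self.calls[(sid, locus)] = (call[0],)
                elif len(call) != 1:
                    offenders.append((sid, locus, call))
            else:
                if len(call) == 1:
                    # single-label female cell: homozygote shorthand
                    self.calls[(sid, locus)] = (call[0], call[0])
                elif len(call) == 2:
                    self.calls[(sid, locus)] = tuple(sorted(call))
                else:
                    raise GenotypeParseError(
                        f"female {sid!r} at {locus!r}: {len(call)} alleles"
                    )
        if offenders:
            detail = ", ".join(
                f"{sid}@{locus}={'/'.join(map(str, call))}"
                for sid, locus, call in offenders
            )
            raise HemizygosityError(
                f"male samples with two distinct alleles at an X locus: {detail}"
            )

    @property
    def males(self) -> list[Sample]:
        return [s for s in self.samples if s.sex == "male"]

    @property
    def females(self) -> list[Sample]:
        return [s for s in self.samples if s.sex == "female"]

    @property
    def n_males(self) -> int:
        return len(self.males)

    @property
    def n_females(self) -> int:
        return len(self.females)

    def call(self, sample_id: str, locus: str) -> Call | None:
        return self.calls.get((sample_id, locus))

    def male_alleles(self, locus: str) -> list[AlleleLabel]:
        """Hemizygous allele of every male with a call at *locus*."""
        self._check_locus(locus)
        return [
            self.calls[(s.sample_id, locus)][0]
            for s in self.males
            if (s.sample_id, locus) in self.calls
        ]

    def female_genotypes(self, locus: str) -> list[tuple[AlleleLabel, AlleleLabel]]:
        """Unordered genotype pair of every female with a call at *locus*."""
        self._check_locus(locus)
        out = []
        for s in self.females:
            call = self.calls.get((s.sample_id, locus))
            if call is not None:
                out.append((call[0], call[1]))
        return out

    def _check_locus(self, locus: str) -> None:
        if locus not in self.loci:
            raise KeyError(f"unknown locus {locus!r}")


# -- reading ---------------------------------------------------------------


def _sniff_delimiter(path: Path) -> str:
    head = path.open(encoding="utf-8").readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def _parse_sex(token: str, row: int) -> str:
    sex = _SEX_CODES.get(token.strip().lower())
    if sex is None:
        raise GenotypeParseError(f"row {row}: unknown sex code {token!r}")
    return sex


def read_genotype_table(path: str | Path, dialect: str = "auto") -> GenotypeTable:
    """Read a sex-annotated genotype table (CSV or TSV).

    Parameters
    ----------
    path : file path
        Header row must name the sample-id column, the sex column, then loci.
    dialect : {"auto", "slash-combined", "two-column"}
        ``auto`` detects two-column layout from duplicated locus headers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    delim = _sniff_delimiter(path)
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise GenotypeParseError(f"{path}: empty file") from None
        rows = [r for r in reader if any(cell.strip() for cell in r)]

    header = [h.strip() for h in header]
    if len(header) < 3:
        raise GenotypeParseError(f"{path}: header must name sample id, sex, loci")
    locus_cells = header[2:]

    if dialect == "auto":
        paired = (
            len(locus_cells) % 2 == 0
            and len(locus_cells) > 0
            and all(
                locus_cells[i] == locus_cells[i + 1] or not locus_cells[i + 1]
                for i in range(0, len(locus_cells), 2)
            )
        )
        dialect = "two-column" if paired else "slash-combined"
    if dialect not in ("slash-combined", "two-column"):
        raise ValueError(f"unknown dialect {dialect!r}")

    if dialect == "two-column":
        loci = [locus_cells[i] for i in range(0, len(locus_cells), 2)]
    else:
        loci = list(locus_cells)

    samples: list[Sample] = []
    calls: dict[tuple[str, str], Call] = {}
    for rownum, row in enumerate(rows, start=2):
        if len(row) < 2:
            raise GenotypeParseError(f"row {rownum}: too few columns")
        sid = row[0].strip()
        sex = _parse_sex(row[1], rownum)
        samples.append(Sample(sid, sex))
        cells = row[2:]
        for j, locus in enumerate(loci):
            if dialect == "two-column":
                raw = cells[2 * j : 2 * j + 2]
                tokens = [c.strip() for c in raw]
                tokens = [t for t in tokens if t.lower() not in _MISSING_TOKENS]
            else:
                cell = cells[j].strip() if j < len(cells) else ""
                if cell.lower() in _MISSING_TOKENS:
                    tokens = []
                else:
                    tokens = [t for t in cell.split("/") if t.strip()]
            if not tokens:
                continue
            try:
                labels = tuple(AlleleLabel.parse(t) for t in tokens)
            except GenotypeParseError as exc:
                raise GenotypeParseError(
                    f"row {rownum}, locus {locus}: {exc}"
                ) from None
            calls[(sid, locus)] = labels

    return GenotypeTable(samples=samples, loci=loci, calls=calls)


# -- writing ---------------------------------------------------------------


def write_genotype_table(
    table: GenotypeTable, path: str | Path, dialect: str = "slash-combined"
) -> None:
    """Write *table* back to CSV/TSV (delimiter from the file extension)."""
    path = Path(path)
    delim = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        if dialect == "slash-combined":
            writer.writerow(["sample_id", "sex", *table.loci])
            for s in table.samples:
                row = [s.sample_id, s.sex]
                for locus in table.loci:
                    call = table.call(s.sample_id, locus)
                    row.append("" if call is None else "/".join(map(str, call)))
                writer.writerow(row)
        elif dialect == "two-column":
            head = ["sample_id", "sex"]
            for locus in table.loci:
                head += [locus, locus]
            writer.writerow(head)
            for s in table.samples:
                row = [s.sample_id, s.sex]
                for locus in table.loci:
                    call = table.call(s.sample_id, locus)
                    if call is None:
                        row += ["", ""]
                    elif len(call) == 1:
                        row += [str(call[0]), ""]
                    else:
                        row += [str(call[0]), str(call[1])]
                writer.writerow(row)
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def write_genepop(
    table: GenotypeTable, path: str | Path, title: str = "xstrkit export"
) -> dict[str, dict[AlleleLabel, str]]:
    """Export to the Genepop dialect for cross-validation of the exact tests.

    Alleles at each locus are recoded to 3-digit integer codes in sorted label
    order.  Females are written as 6-digit diploid genotypes, males as single
    3-digit haploid codes (Genepop's haploid convention).  Returns the
    per-locus label->code mapping.
    """
    if not table.samples or not table.loci:
        raise ValueError("empty table: nothing to export")
    coding: dict[str, dict[AlleleLabel, str]] = {}
    for locus in table.loci:
        alleles = sorted(
            set(table.male_alleles(locus))
            | {a for g in table.female_genotypes(locus) for a in g}
        )
        if len(alleles) > 999:
            raise ValueError(f"{locus}: more than 999 alleles unsupported")
        coding[locus] = {a: f"{i + 1:03d}" for i, a in enumerate(alleles)}

    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(title + "\n")
        for locus in table.loci:
            fh.write(locus + "\n")
        fh.write("Pop\n")
        for s in table.samples:
            fields = []
            for locus in table.loci:
                call = table.call(s.sample_id, locus)
                if call is None:
                    fields.append("000000" if s.sex == "female" else "000")
                elif s.sex == "female":
                    fields.append(coding[locus][call[0]] + coding[locus][call[1]])
                else:
                    fields.append(coding[locus][call[0]])
            fh.write(f"{s.sample_id} , " + " ".join(fields) + "\n")
    return coding
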