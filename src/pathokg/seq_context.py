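"""Genomic context-window extraction for variant embedding.

Each variant is embedded from a fixed-length window of the *alternative*
(post-variant) sequence around its locus.  All coordinates are 1-based
inclusive (ClinVar/VCF convention).  The window is nominally centered on the
variant — the variant base sits at 0-based offset ``W // 2`` — and when the
nominal window would overhang a chromosome end by ``n`` positions it is
shifted by exactly ``n`` toward the interior so it always fits.

Per variant class:

* **snv** — extract the reference window, substitute the alternative base at
  the variant offset.
* **insertion** — extract the reference window around the anchor position,
  splice the inserted payload in at the window midpoint, then trim
  ``len(payload) // 2`` bases from the left and the remainder from the right
  to restore length ``W``.
* **deletion** — extract an extended window of length ``W + len(deleted)``
  centered on the middle of the deleted segment, then excise the segment.
* **indel** — deletion followed by insertion: excise the reference segment
  from the extended window, splice the alternative payload in at the excision
  point, and trim back to ``W`` keeping the payload at the same midpoint
  offset an insertion would occupy.

All four operations are pure functions of (chromosome, record, W).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from pathokg.errors import ParseError, RangeError, ReferenceAlleleError, WindowError

VAR_CLASSES = ("snv", "insertion", "deletion", "indel")
DNA_ALPHABET = frozenset("ACGTN")

ALLOWED_REVIEW_STATUSES = (
    "practice guideline",
    "reviewed by expert panel",
    "criteria provided, multiple submitters, no conflicts",
    "criteria provided, single submitter",
)


@dataclass(frozen=True)
class ChromSeq:
    """One chromosome; ``seq`` uses the {A,C,G,T,N} alphabet, 1-based coordinates."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise RangeError(f"chromosome {self.name!r} is empty")
        bad = set(self.seq.upper()) - DNA_ALPHABET
        if bad:
            raise ParseError(f"chromosome {self.name!r} has non-DNA characters {sorted(bad)}")
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)

    def base(self, pos: int) -> str:
        """Base at 1-based position ``pos``."""
        return self.seq[pos - 1]

    def slice(self, start: int, end: int) -> str:
        """Substring for the 1-based inclusive range [start, end]."""
        return self.seq[start - 1 : end]


@dataclass
class VariantRecord:
    """A single variant with ClinVar-style clinical metadata.

    ``ref``/``alt`` follow the explicit-allele dialect: for an insertion the
    VCF-style anchored form (ref ``A``, alt ``AGG``) is also accepted and is
    normalized to a pure payload anchored after ``pos``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    var_class: str
    gene: str
    clinical_label: str = "other"
    review_status: str = ""
    origin: str = "germline"
    assembly: str = "GRCh38"
    submission_date: str | None = None
    diseases: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.var_class not in VAR_CLASSES:
            raise RangeError(f"unknown variant class {self.var_class!r}")
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()

    @property
    def variant_id(self) -> str:
        return f"var:{self.chrom}:{self.pos}:{self.ref or '-'}>{self.alt or '-'}"

    def insertion_payload(self) -> tuple[int, str]:
        """(anchor position, payload) for an insertion record.

        A record with empty ref inserts after ``pos``; a VCF-style anchored
        record (alt starting with ref, single-base ref) likewise inserts the
        suffix after ``pos``.
        """
        if self.ref == "":
            return self.pos, self.alt
        if len(self.ref) == 1 and self.alt.startswith(self.ref) and len(self.alt) > 1:
            return self.pos, self.alt[1:]
        raise ReferenceAlleleError(
            f"{self.variant_id}: cannot interpret ref={self.ref!r} alt={self.alt!r} as insertion"
        )


def resolve_window(center: int, W: int, chrom_len: int) -> tuple[int, int]:
    """1-based inclusive window of length ``W`` around ``center``.

    Without boundary effects the window starts at ``center - W // 2`` so the
    center occupies 0-based offset ``W // 2``.  If that placement overflows a
    chromosome end by ``n`` positions, the window is shifted by ``n`` toward
    the other side.
    """
    if not 1 <= W <= chrom_len:
        raise WindowError(f"window length {W} infeasible for chromosome of length {chrom_len}")
    if not 1 <= center <= chrom_len:
        raise RangeError(f"center {center} outside chromosome of length {chrom_len}")
    start = center - W // 2
    end = start + W - 1
    if start < 1:
        end += 1 - start
        start = 1
    elif end > chrom_len:
        start -= end - chrom_len
        end = chrom_len
    return start, end


def _check_ref(chrom: ChromSeq, pos: int, ref: str, variant_id: str) -> None:
    observed = chrom.slice(pos, pos + len(ref) - 1)
    if observed != ref:
        raise ReferenceAlleleError(
            f"{variant_id}: reference allele {ref!r} does not match chromosome "
            f"{chrom.name!r} at position {pos} (found {observed!r})"
        )


def extract_snv(chrom: ChromSeq, v: VariantRecord, W: int) -> str:
    """Window with the single reference base replaced by the alternative base."""
    if len(v.ref) != 1 or len(v.alt) != 1:
        raise ReferenceAlleleError(f"{v.variant_id}: snv requires single-base ref and alt")
    _check_ref(chrom, v.pos, v.ref, v.variant_id)
    start, end = resolve_window(v.pos, W, len(chrom))
    offset = v.pos - start
    window = chrom.slice(start, end)
    return window[:offset] + v.alt + window[offset + 1 :]


def _truncate_inserted(seq: str, surplus: int, left: int) -> str:
    """Drop ``surplus`` characters: ``left`` from the left, the rest from the right."""
    right = surplus - left
    return seq[left : len(seq) - right]


def extract_insertion(chrom: ChromSeq, v: VariantRecord, W: int) -> str:
    """Reference window with the payload spliced in at the midpoint, trimmed to W.

    The trim removes ``len(payload) // 2`` bases from the left and the
    remainder from the right (odd payloads lose one extra base on the 3' side).
    """
    anchor, payload = v.insertion_payload()
    if payload == "":
        raise ReferenceAlleleError(f"{v.variant_id}: empty insertion payload")
    start, end = resolve_window(anchor, W, len(chrom))
    window = chrom.slice(start, end)
    mid = W // 2
    widened = window[:mid] + payload + window[mid:]
    return _truncate_inserted(widened, len(payload), len(payload) // 2)


def _deletion_segment(v: VariantRecord) -> tuple[int, int]:
    if v.ref == "":
        raise ReferenceAlleleError(f"{v.variant_id}: deletion requires a nonempty ref segment")
    return v.pos, v.pos + len(v.ref) - 1


def _excised_window(chrom: ChromSeq, v: VariantRecord, W: int) -> tuple[str, int]:
    """Excise the ref segment from the extended window.

    Returns the length-W alternative window and the 0-based excision offset
    within it.
    """
    seg_start, seg_end = _deletion_segment(v)
    _check_ref(chrom, seg_start, v.ref, v.variant_id)
    d = seg_end - seg_start + 1
    center = (seg_start + seg_end) // 2
    start, end = resolve_window(center, W + d, len(chrom))
    if not (start <= seg_start and seg_end <= end):
        raise WindowError(
            f"{v.variant_id}: deleted segment [{seg_start}, {seg_end}] escapes "
            f"extended window [{start}, {end}]"
        )
    window = chrom.slice(start, end)
    k = seg_start - start
    return window[:k] + window[k + d :], k


def extract_deletion(chrom: ChromSeq, v: VariantRecord, W: int) -> str:
    """Extended window of length W + len(deleted) with the deleted segment excised."""
    out, _ = _excised_window(chrom, v, W)
    return out


def extract_indel(chrom: ChromSeq, v: VariantRecord, W: int) -> str:
    """Deletion followed by insertion of the alternative payload.

    The payload is spliced in at the excision point and the sequence trimmed
    back to W such that the payload start lands at offset
    ``W // 2 - len(alt) // 2`` — the same alignment a pure insertion produces,
    which also makes a 1-base-for-1-base indel coincide with the snv
    extraction at the same locus.
    """
    excised, k = _excised_window(chrom, v, W)
    t = len(v.alt)
    if t == 0:
        return excised
    widened = excised[:k] + v.alt + excised[k:]
    left = k - (W // 2 - t // 2)
    left = min(max(left, 0), t)
    return _truncate_inserted(widened, t, left)


_DISPATCH = {
    "snv": extract_snv,
    "insertion": extract_insertion,
    "deletion": extract_deletion,
    "indel": extract_indel,
}


def extract_context(chrom: ChromSeq, v: VariantRecord, W: int) -> str:
    """Alternative-allele context window for any variant class."""
    return _DISPATCH[v.var_class](chrom, v, W)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, ChromSeq]:
    """Load a (possibly multi-record, line-wrapped) FASTA into ChromSeq objects."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = ChromSeq(rec.id, str(rec.seq))
    if not records:
        raise ParseError(f"no FASTA records found in {path}")
    return records


def write_fasta(chroms: dict[str, ChromSeq] | list[ChromSeq], path, width: int = 70) -> None:
    seqs = chroms.values() if isinstance(chroms, dict) else chroms
    with open(path, "w", encoding="utf-8") as fh:
        for c in seqs:
            fh.write(f">{c.name}\n")
            for i in range(0, len(c.seq), width):
                fh.write(c.seq[i : i + width] + "\n")


_VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "class",
    "gene",
    "label",
    "review_status",
    "origin",
    "assembly",
    "date",
    "diseases",
]


def write_variant_table(variants: list[VariantRecord], path) -> None:
    """Write variants as a UTF-8 TSV; diseases are semicolon-separated."""
    import csv

    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_VARIANT_COLUMNS)
        for v in variants:
            w.writerow(
                [
                    v.chrom,
                    v.pos,
                    v.ref,
                    v.alt,
                    v.var_class,
                    v.gene,
                    v.clinical_label,
                    v.review_status,
                    v.origin,
                    v.assembly,
                    v.submission_date or "",
                    ";".join(v.diseases),
                ]
            )


def read_variant_table(path) -> list[VariantRecord]:
    """Read the variant TSV written by :func:`write_variant_table`."""
    import csv

    out = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _VARIANT_COLUMNS:
            raise ParseError(f"expected header {_VARIANT_COLUMNS}", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_VARIANT_COLUMNS):
                raise ParseError(f"expected {len(_VARIANT_COLUMNS)} columns", line=lineno)
            try:
                out.append(
                    VariantRecord(
                        chrom=row[0],
                        pos=int(row[1]),
                        ref=row[2],
                        alt=row[3],
                        var_class=row[4],
                        gene=row[5],
                        clinical_label=row[6],
                        review_status=row[7],
                        origin=row[8],
                        assembly=row[9],
                        submission_date=row[10] or None,
                        diseases=[d for d in row[11].split(";") if d],
                    )
                )
            except (ValueError, RangeError) as exc:
                raise ParseError(str(exc), line=lineno) from exc
    return out
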