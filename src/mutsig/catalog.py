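"""Somatic variant import and mutation-type cataloging.

This module turns somatic single-nucleotide variants (SNVs) into
pyrimidine-oriented mutation-type counts. An SNV is annotated with its
flanking genomic context and, when the mutated reference base is a purine
(A/G), the whole context window is reverse-complemented so that the
reference base at the mutated position is always a pyrimidine (C/T) —
the orientation convention used by COSMIC. With one base of context on
each side this yields the standard 96 tri-nucleotide mutation types;
wider contexts (e.g. two 5' bases, the tetra-nucleotide scheme) are
supported through :class:`ContextShape`.
"""

from __future__ import annotations

import itertools
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Pyrimidine-reference substitution classes in canonical (COSMIC) order.
SUBSTITUTION_CLASSES: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_VALID_BASES = frozenset("ACGT")
_PYRIMIDINES = frozenset("CT")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class VariantRecord:
    """One somatic substitution call.

    Coordinates are 1-based; ``ref``/``alt`` are the alleles as reported
    by the variant file (genomic strand, not yet pyrimidine-oriented).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    sample: str


@dataclass(frozen=True)
class ContextShape:
    """Width of the retained context around the mutated base.

    ``n_up`` bases are kept 5' and ``n_down`` bases 3' of the mutated
    position *on the pyrimidine-oriented strand*. The standard
    tri-nucleotide scheme is ``(1, 1)``; the 5'-extended tetra-nucleotide
    scheme is ``(2, 1)``.
    """

    n_up: int = 1
    n_down: int = 1

    def __post_init__(self) -> None:
        if self.n_up < 0 or self.n_down < 0:
            raise ValueError("context widths must be non-negative")

    @property
    def window(self) -> int:
        """Half-width of the symmetric genomic window to fetch."""
        return max(self.n_up, self.n_down)

    @property
    def n_labels(self) -> int:
        return 4 ** (self.n_up + self.n_down) * 6


TRI = ContextShape(1, 1)
TETRA = ContextShape(2, 1)

_BRACKET_RE = re.compile(r"^([ACGT]*)\[([CT])>([ACGT])\]([ACGT]*)$")
_PIPE_RE = re.compile(r"^([ACGT]*)\|([CT]) ?> ?([ACGT])\|([ACGT]*)$")


def render_label(up: str, ref: str, alt: str, down: str, style: str = "bracket") -> str:
    """Format a mutation type. ``bracket`` gives ``A[C>T]G``; ``pipe``
    gives the ``A|C > T|G`` dialect."""
    if style == "bracket":
        return f"{up}[{ref}>{alt}]{down}"
    if style == "pipe":
        return f"{up}|{ref} > {alt}|{down}"
    raise ValueError(f"unknown render style: {style!r}")


def parse_label(label: str) -> tuple[str, str, str, str]:
    """Parse a bracket- or pipe-style label into (up, ref, alt, down)."""
    m = _BRACKET_RE.match(label) or _PIPE_RE.match(label)
    if m is None:
        raise ValueError(f"cannot parse mutation-type label: {label!r}")
    return m.group(1), m.group(2), m.group(3), m.group(4)


@dataclass(frozen=True)
class MutationTypeDictionary:
    """Ordered set of pyrimidine-oriented mutation-type labels."""

    shape: ContextShape
    labels: tuple[str, ...]
    render_style: str = "bracket"

    def __len__(self) -> int:
        return len(self.labels)

    def render(self, up: str, ref: str, alt: str, down: str) -> str:
        return render_label(up, ref, alt, down, self.render_style)

    def index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}


def build_dictionary(shape: ContextShape = TRI, render_style: str = "bracket") -> MutationTypeDictionary:
    """Enumerate all mutation-type labels for a context shape.

    Substitution classes come in canonical order (C>A, C>G, C>T, T>A,
    T>C, T>G); within a class, contexts are lexicographic on the
    concatenated 5' + 3' flanks. The tri-nucleotide shape yields 96
    labels, the (2, 1) tetra shape 384.
    """
    labels = []
    n_ctx = shape.n_up + shape.n_down
    for cls in SUBSTITUTION_CLASSES:
        ref, alt = cls.split(">")
        for ctx in itertools.product("ACGT", repeat=n_ctx):
            up = "".join(ctx[: shape.n_up])
            down = "".join(ctx[shape.n_up :])
            labels.append(render_label(up, ref, alt, down, render_style))
    return MutationTypeDictionary(shape=shape, labels=tuple(labels), render_style=render_style)


class ReferenceStore:
    """Genome sequence access by 1-based inclusive coordinates.

    Backed either by an in-memory mapping of chromosome name to sequence
    or by an indexed FASTA file (via :mod:`pyfaidx`). Sequences are
    returned upper-case; out-of-bounds queries raise.
    """

    def __init__(self, sequences: Mapping[str, str] | None = None, fasta=None):
        if (sequences is None) == (fasta is None):
            raise ValueError("provide exactly one of sequences or fasta")
        self._seqs = {c: s.upper() for c, s in sequences.items()} if sequences is not None else None
        self._fasta = fasta

    @classmethod
    def from_sequences(cls, sequences: Mapping[str, str]) -> "ReferenceStore":
        return cls(sequences=sequences)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceStore":
        import pyfaidx

        return cls(fasta=pyfaidx.Fasta(str(path), sequence_always_upper=True))

    @property
    def chroms(self) -> list[str]:
        if self._seqs is not None:
            return list(self._seqs)
        return list(self._fasta.keys())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms

    def length(self, chrom: str) -> int:
        if self._seqs is not None:
            return len(self._seqs[chrom])
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``chrom`` from ``start`` to ``end``, 1-based inclusive."""
        if chrom not in self:
            raise KeyError(f"chromosome {chrom!r} not in reference")
        if start < 1 or end > self.length(chrom) or start > end:
            raise IndexError(
                f"range {start}-{end} outside bounds of {chrom!r} (1-{self.length(chrom)})"
            )
        if self._seqs is not None:
            return self._seqs[chrom][start - 1 : end]
        return str(self._fasta[chrom][start - 1 : end]).upper()


def normalize_chrom(name: str, strip_chr: bool) -> str:
    if strip_chr and name.lower().startswith("chr"):
        return name[3:]
    return name


def read_variants_vcf(
    path: str | Path,
    sample_mode: str = "per-file",
    sample_column: str | None = None,
) -> list[VariantRecord]:
    """Read SNV candidate rows from a VCF body.

    Only the first five standard columns (CHROM, POS, ID, REF, ALT) are
    interpreted; header lines start with ``#``. Multi-allelic ALT fields
    are split on commas into one record per alternate allele. In
    ``per-file`` mode the sample name is the file stem; in
    ``from-column`` mode it is taken from the named column of the
    ``#CHROM`` header line.
    """
    if sample_mode not in ("per-file", "from-column"):
        raise ValueError(f"unknown sample_mode: {sample_mode!r}")
    path = Path(path)
    file_sample = path.stem
    sample_idx: int | None = None
    records: list[VariantRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if sample_mode == "from-column" and line.startswith("#CHROM"):
                    header = line.lstrip("#").split("\t")
                    if sample_column not in header:
                        raise ValueError(
                            f"sample column {sample_column!r} not in VCF header"
                        )
                    sample_idx = header.index(sample_column)
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(
                    f"{path.name}: malformed VCF row {lineno}: expected >=5 columns, got {len(fields)}"
                )
            chrom, pos, _id, ref, alt_field = fields[:5]
            if sample_mode == "from-column":
                if sample_idx is None:
                    raise ValueError(
                        "from-column mode requires a #CHROM header line naming the sample column"
                    )
                sample = fields[sample_idx]
            else:
                sample = file_sample
            for alt in alt_field.split(","):
                records.append(
                    VariantRecord(chrom=chrom, pos=int(pos), ref=ref.upper(), alt=alt.upper(), sample=sample)
                )
    return records


DEFAULT_MAF_COLUMNS = {
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
    "sample": "Tumor_Sample_Barcode",
}


def read_variants_maf(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[VariantRecord]:
    """Read variants from a MAF-style tab-delimited table.

    ``column_map`` maps the semantic fields (chrom, pos, ref, alt,
    sample) to header names; the default uses the TCGA MAF conventions
    and accepts ``Start_position`` as a fallback spelling for the
    position column. Rows with missing values in any mapped column are
    dropped (the count is logged).
    """
    cmap = dict(DEFAULT_MAF_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, low_memory=False)
    if cmap["pos"] not in df.columns and "Start_position" in df.columns and not column_map:
        cmap["pos"] = "Start_position"
    for sem, col in cmap.items():
        if col not in df.columns:
            raise ValueError(f"required MAF column {col!r} (for {sem}) absent from header")
    sub = df[[cmap[s] for s in ("chrom", "pos", "ref", "alt", "sample")]]
    n_before = len(sub)
    sub = sub.dropna()
    n_dropped = n_before - len(sub)
    if n_dropped:
        logger.info("read_variants_maf: dropped %d rows with missing values", n_dropped)
    return [
        VariantRecord(chrom=str(c), pos=int(p), ref=str(r).upper(), alt=str(a).upper(), sample=str(s))
        for c, p, r, a, s in sub.itertuples(index=False)
    ]


def filter_snvs(records: Iterable[VariantRecord]) -> tuple[list[VariantRecord], Counter]:
    """Keep single-nucleotide substitutions; tally everything else.

    A record survives when ref and alt are each one of A/C/G/T and
    differ. Indels, multi-nucleotide variants and '-' alleles are
    tallied as ``indel_or_mnv``; 'N' or other single-character alleles
    as ``ambiguous_base``; identical alleles as ``ref_equals_alt``.
    """
    kept: list[VariantRecord] = []
    report: Counter = Counter()
    for rec in records:
        if len(rec.ref) != 1 or len(rec.alt) != 1 or "-" in (rec.ref, rec.alt):
            report["indel_or_mnv"] += 1
        elif rec.ref not in _VALID_BASES or rec.alt not in _VALID_BASES:
            report["ambiguous_base"] += 1
        elif rec.ref == rec.alt:
            report["ref_equals_alt"] += 1
        else:
            kept.append(rec)
    return kept, report


def mutation_type(
    record: VariantRecord,
    store: ReferenceStore,
    shape: ContextShape = TRI,
    render_style: str = "bracket",
) -> tuple[str | None, str | None]:
    """Pyrimidine-oriented mutation type of one SNV.

    Fetches the symmetric window ``[pos - w, pos + w]`` with
    ``w = max(n_up, n_down)``, checks that the central base matches the
    record's reference allele, reverse-complements the whole window and
    the alternate allele when the reference base is a purine, then
    slices ``n_up`` bases 5' and ``n_down`` bases 3' of the (now
    pyrimidine) central base.

    Returns ``(label, None)`` on success or ``(None, reason)`` when the
    variant cannot be typed (``ref_mismatch``, ``edge``,
    ``ambiguous_context``). An absent chromosome raises ``KeyError``.
    """
    if record.chrom not in store:
        raise KeyError(f"chromosome {record.chrom!r} not in reference store")
    w = shape.window
    start, end = record.pos - w, record.pos + w
    if start < 1 or end > store.length(record.chrom):
        return None, "edge"
    window = store.fetch(record.chrom, start, end)
    if "N" in window:
        return None, "ambiguous_context"
    if window[w] != record.ref:
        return None, "ref_mismatch"
    alt = record.alt
    if record.ref in ("A", "G"):
        window = reverse_complement(window)
        alt = reverse_complement(alt)
    up = window[w - shape.n_up : w]
    down = window[w + 1 : w + 1 + shape.n_down]
    return render_label(up, window[w], alt, down, render_style), None


def count_mutation_types(
    records: Sequence[VariantRecord],
    store: ReferenceStore,
    dictionary: MutationTypeDictionary,
) -> tuple[pd.DataFrame, Counter]:
    """Tabulate per-sample mutation-type counts.

    Returns an ``m x n`` integer DataFrame (rows = the dictionary's
    labels in order, columns = samples by first appearance) plus a tally
    of variants rejected during typing. The matrix total plus the tally
    equals the number of input records.
    """
    label_idx = dictionary.index()
    samples: list[str] = []
    counts: dict[tuple[int, str], int] = {}
    rejections: Counter = Counter()
    for rec in records:
        label, reason = mutation_type(rec, store, dictionary.shape, dictionary.render_style)
        if label is None:
            rejections[reason] += 1
            continue
        if label not in label_idx:
            rejections["label_not_in_dictionary"] += 1
            continue
        if rec.sample not in samples:
            samples.append(rec.sample)
        key = (label_idx[label], rec.sample)
        counts[key] = counts.get(key, 0) + 1
    mat = pd.DataFrame(0, index=list(dictionary.labels), columns=samples, dtype=int)
    for (i, sample), c in counts.items():
        mat.iloc[i, mat.columns.get_loc(sample)] = c
    return mat, rejections


def simplify_context(profile: pd.DataFrame) -> pd.DataFrame:
    """Collapse a 5'-extended (tetra) profile onto tri-nucleotide types.

    Rows whose labels embed the same tri-nucleotide mutation type (the
    immediate 5' base, the substitution and the 3' base) are summed;
    the result has the 96 canonical tri rows and identical column sums.
    Works for count matrices and for signature matrices alike.
    """
    tri_dict = build_dictionary(TRI)
    tetra_shape = TETRA
    mapped = []
    for label in profile.index:
        up, ref, alt, down = parse_label(str(label))
        if len(up) != tetra_shape.n_up or len(down) != tetra_shape.n_down:
            raise ValueError(
                f"label {label!r} does not have tetra-nucleotide shape (2 up, 1 down)"
            )
        mapped.append(render_label(up[-1:], ref, alt, down, "bracket"))
    out = profile.groupby(pd.Index(mapped, name=profile.index.name)).sum()
    return out.reindex(tri_dict.labels).fillna(0.0)
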