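"""Panel data model and I/O for targeted circRNA back-splice junction panels.

A panel entry describes one circRNA by the two exons flanking its back-splice
junction (BSJ) — the circle's last exon (splice donor of the BSJ) and its first
exon (splice acceptor, the "3' BSJ exon" in read orientation) — plus the exon
that is spliced to the acceptor exon in the canonical linear transcript.

Coordinates are 0-based half-open (BED convention) throughout; strand-aware
helpers return transcript-sense sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: multiplexing recommendation for one sequencing reaction, not a hard limit
PANEL_SIZE_RECOMMENDED_MAX = 110

PANEL_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "score",
    "strand",
    "host_gene",
    "donor_exon",
    "acceptor_exon",
    "upstream_linear_exon",
]


class PanelError(ValueError):
    """Malformed or invalid panel input."""


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise PanelError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise PanelError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def region(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @classmethod
    def from_region(cls, region: str, strand: str) -> "GenomicInterval":
        try:
            chrom, span = region.rsplit(":", 1)
            start, end = span.split("-")
            return cls(chrom, int(start), int(end), strand)
        except (ValueError, TypeError) as exc:
            raise PanelError(f"cannot parse region {region!r}") from exc


@dataclass(frozen=True)
class CircTarget:
    """One circRNA target: BSJ-flanking exons plus the linear neighbour exon."""

    target_id: str
    host_gene: str
    donor_exon: GenomicInterval
    acceptor_exon: GenomicInterval
    upstream_linear_exon: GenomicInterval

    def __post_init__(self) -> None:
        ivs = (self.donor_exon, self.acceptor_exon, self.upstream_linear_exon)
        chroms = {iv.chrom for iv in ivs}
        strands = {iv.strand for iv in ivs}
        if len(chroms) != 1 or len(strands) != 1:
            raise PanelError(
                f"{self.target_id}: all exons must share chrom and strand"
            )
        if self.strand == "+":
            if not self.upstream_linear_exon.end <= self.acceptor_exon.start:
                raise PanelError(
                    f"{self.target_id}: upstream linear exon must lie 5' of the "
                    "acceptor exon"
                )
            if not self.acceptor_exon.start < self.donor_exon.end:
                raise PanelError(
                    f"{self.target_id}: acceptor exon must lie 5' of the BSJ donor"
                )
        else:
            if not self.acceptor_exon.end <= self.upstream_linear_exon.start:
                raise PanelError(
                    f"{self.target_id}: upstream linear exon must lie 5' of the "
                    "acceptor exon (transcript order, - strand)"
                )
            if not self.donor_exon.start < self.acceptor_exon.end:
                raise PanelError(
                    f"{self.target_id}: acceptor exon must lie 5' of the BSJ donor "
                    "(transcript order, - strand)"
                )

    @property
    def chrom(self) -> str:
        return self.acceptor_exon.chrom

    @property
    def strand(self) -> str:
        return self.acceptor_exon.strand

    @property
    def bsj_donor(self) -> GenomicInterval:
        """Single-base interval of the BSJ splice-donor base (donor exon 3' end)."""
        e = self.donor_exon
        if self.strand == "+":
            return GenomicInterval(e.chrom, e.end - 1, e.end, e.strand)
        return GenomicInterval(e.chrom, e.start, e.start + 1, e.strand)

    @property
    def bsj_acceptor(self) -> GenomicInterval:
        """Single-base interval of the BSJ splice-acceptor base (acceptor exon 5' end)."""
        e = self.acceptor_exon
        if self.strand == "+":
            return GenomicInterval(e.chrom, e.start, e.start + 1, e.strand)
        return GenomicInterval(e.chrom, e.end - 1, e.end, e.strand)

    @property
    def circle_span(self) -> GenomicInterval:
        """Genomic span of the circle (acceptor exon start to donor exon end)."""
        lo = min(self.acceptor_exon.start, self.donor_exon.start)
        hi = max(self.acceptor_exon.end, self.donor_exon.end)
        return GenomicInterval(self.chrom, lo, hi, self.strand)

    def acceptor_key(self) -> tuple:
        """Key identifying the shared 3' BSJ exon (one FSS primer per key)."""
        e = self.acceptor_exon
        return (self.host_gene, e.chrom, e.start, e.end, e.strand)


@dataclass
class Panel:
    targets: list = field(default_factory=list)
    name: str = "panel"

    def __post_init__(self) -> None:
        if len(self.targets) < 1:
            raise PanelError("panel must contain at least one target")
        ids = [t.target_id for t in self.targets]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise PanelError(f"duplicate target_id(s): {sorted(dupes)}")
        if len(self.targets) > PANEL_SIZE_RECOMMENDED_MAX:
            warnings.warn(
                f"panel has {len(self.targets)} targets; more than "
                f"{PANEL_SIZE_RECOMMENDED_MAX} in one sequencing reaction exceeds "
                "the multiplexing recommendation",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.targets)

    def __iter__(self):
        return iter(self.targets)

    def get(self, target_id: str) -> CircTarget:
        for t in self.targets:
            if t.target_id == target_id:
                return t
        raise KeyError(target_id)


GenomeLike = Union[str, Path, Mapping[str, str]]


class GenomeSource:
    """Uniform access to chromosome sequence from a FASTA path or a dict.

    A FASTA path is opened with pyfaidx (indexed, lazy); a plain mapping of
    chromosome name to sequence string is used directly (handy for toy genomes).
    """

    def __init__(self, source: GenomeLike):
        if isinstance(source, GenomeSource):
            self._fasta = source._fasta
            self._dict = source._dict
        elif isinstance(source, (str, Path)):
            import pyfaidx

            self._fasta = pyfaidx.Fasta(str(source))
            self._dict = None
        elif isinstance(source, Mapping):
            self._fasta = None
            self._dict = {k: v.upper() for k, v in source.items()}
        else:
            raise TypeError(f"unsupported genome source: {type(source)!r}")

    def chrom_len(self, chrom: str) -> int:
        if self._dict is not None:
            if chrom not in self._dict:
                raise PanelError(f"chromosome {chrom!r} not in genome")
            return len(self._dict[chrom])
        if chrom not in self._fasta:
            raise PanelError(f"chromosome {chrom!r} not in genome")
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        n = self.chrom_len(chrom)
        if not (0 <= start < end <= n):
            raise PanelError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds (len {n})"
            )
        if self._dict is not None:
            return self._dict[chrom][start:end]
        return str(self._fasta[chrom][start:end]).upper()

    def transcript_seq(self, iv: GenomicInterval) -> str:
        """Transcript-sense sequence of an interval (reverse-complemented on -)."""
        seq = self.fetch(iv.chrom, iv.start, iv.end)
        return reverse_complement(seq) if iv.strand == "-" else seq


def read_panel(path, genome: GenomeLike | None = None, name: str | None = None) -> Panel:
    """Read a panel TSV (BED6 + host_gene / donor_exon / acceptor_exon /
    upstream_linear_exon columns) and validate it, optionally against a genome.
    """
    path = Path(path)
    targets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < len(PANEL_COLUMNS):
                raise PanelError(
                    f"{path}:{lineno}: expected {len(PANEL_COLUMNS)} tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                chrom, start, end, tid, _score, strand = fields[:6]
                host, donor, acceptor, upstream = fields[6:10]
                int(start), int(end)  # noqa: B018 - BED span sanity only
                target = CircTarget(
                    target_id=tid,
                    host_gene=host,
                    donor_exon=GenomicInterval.from_region(donor, strand),
                    acceptor_exon=GenomicInterval.from_region(acceptor, strand),
                    upstream_linear_exon=GenomicInterval.from_region(upstream, strand),
                )
            except PanelError as exc:
                raise PanelError(f"{path}:{lineno}: {exc}") from exc
            targets.append(target)
    panel = Panel(targets=targets, name=name or path.stem)
    if genome is not None:
        validate_panel_against_genome(panel, genome)
    return panel


def write_panel(panel: Panel, path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(PANEL_COLUMNS) + "\n")
        for t in panel:
            span = t.circle_span
            fh.write(
                "\t".join(
                    [
                        t.chrom,
                        str(span.start),
                        str(span.end),
                        t.target_id,
                        "0",
                        t.strand,
                        t.host_gene,
                        t.donor_exon.region(),
                        t.acceptor_exon.region(),
                        t.upstream_linear_exon.region(),
                    ]
                )
                + "\n"
            )


def validate_panel_against_genome(panel: Panel, genome: GenomeLike) -> None:
    src = GenomeSource(genome)
    for t in panel:
        for iv in (t.donor_exon, t.acceptor_exon, t.upstream_linear_exon):
            n = src.chrom_len(iv.chrom)
            if iv.end > n:
                raise PanelError(
                    f"{t.target_id}: interval {iv.region()} outside chromosome "
                    f"bounds (len {n})"
                )


def group_targets_by_acceptor_exon(panel: Panel) -> dict:
    """Partition targets by shared 3' BSJ exon within a host gene.

    Circles from the same host gene that share the acceptor exon can be served
    by one first-strand-synthesis primer; the number of groups is the number of
    primers needed.
    """
    groups: dict = {}
    for t in panel:
        groups.setdefault(t.acceptor_key(), []).append(t)
    return groups
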