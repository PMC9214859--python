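"""Per-target junction reference sequences for classification and simulation.

For each target two transcript-sense references are built around the shared
acceptor exon prefix:

- bsj_seq:    last F nt of the circle's donor exon  ++  first D nt of the acceptor exon
- linear_seq: last F nt of the upstream linear exon ++  first D nt of the acceptor exon

The junction sits at offset F in both. D runs from the acceptor exon start
through the FSS primer's 3' terminus (its transcript-5'-most bound base), so a
reference 3' end is exactly where a library read's 3' end is anchored. F
defaults to the read length and is truncated to the shorter of the two 5'-side
exons so the offset is shared.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .panel import GenomeSource, Panel, group_targets_by_acceptor_exon


class ReferenceError_(RuntimeError):
    """Failure to construct a junction reference; message names the target."""


@dataclass(frozen=True)
class JunctionReference:
    target_id: str
    group_id: str
    bsj_seq: str
    linear_seq: str
    junction_offset: int  # = F
    flank_F: int
    flank_D: int
    classifiable: bool = True

    def __post_init__(self) -> None:
        if self.junction_offset != self.flank_F:
            raise ValueError("junction_offset must equal flank_F")
        if (
            self.bsj_seq[self.junction_offset :]
            != self.linear_seq[self.junction_offset :]
        ):
            raise ValueError(
                f"{self.target_id}: acceptor-side suffixes differ between bsj and "
                "linear references"
            )


def build_references(
    panel: Panel,
    primers: list,
    genome,
    flank_F: int = 300,
    min_anchor: int = 10,
) -> list[JunctionReference]:
    """One JunctionReference per target; targets sharing a primer still get
    distinct bsj_seq when their donor exons differ.

    Targets whose donor-side and linear-side flanks coincide over the
    min_anchor bases adjacent to the junction are marked unclassifiable (no
    read can distinguish the two junctions) and excluded from junction calls.
    """
    src = GenomeSource(genome)
    groups = group_targets_by_acceptor_exon(panel)
    primer_by_target: dict = {}
    for p in primers:
        for tid in p.group_targets:
            primer_by_target[tid] = p
    refs = []
    for key, targets in groups.items():
        for t in targets:
            primer = primer_by_target.get(t.target_id)
            if primer is None:
                raise ReferenceError_(
                    f"{t.target_id}: no FSS primer maps to this target"
                )
            try:
                donor_seq = src.transcript_seq(t.donor_exon)
                upstream_seq = src.transcript_seq(t.upstream_linear_exon)
                acceptor_seq = src.transcript_seq(t.acceptor_exon)
            except Exception as exc:
                raise ReferenceError_(f"{t.target_id}: {exc}") from exc
            f = min(flank_F, len(donor_seq), len(upstream_seq))
            d = primer.distance_to_bsj_nt
            if d > len(acceptor_seq):
                raise ReferenceError_(
                    f"{t.target_id}: primer distance {d} exceeds acceptor exon "
                    f"length {len(acceptor_seq)}"
                )
            bsj = donor_seq[-f:] + acceptor_seq[:d]
            lin = upstream_seq[-f:] + acceptor_seq[:d]
            classifiable = bsj[:f] != lin[:f] and (
                bsj[max(0, f - min_anchor) : f] != lin[max(0, f - min_anchor) : f]
            )
            refs.append(
                JunctionReference(
                    target_id=t.target_id,
                    group_id=primer.primer_id,
                    bsj_seq=bsj,
                    linear_seq=lin,
                    junction_offset=f,
                    flank_F=f,
                    flank_D=d,
                    classifiable=classifiable,
                )
            )
    return refs


def primer_cross_matches(primers: list, refs: list[JunctionReference]) -> list[tuple]:
    """Within-panel specificity check: report (primer_id, target_id, kind) for
    every exact occurrence of a primer's specific portion (as the transcript-
    sense window it binds) in a junction reference of a target it does not
    serve. A lightweight stand-in for a genome-wide off-target screen."""
    from .panel import reverse_complement

    hits = []
    for p in primers:
        site = reverse_complement(p.specific_seq)
        for r in refs:
            if r.target_id in p.group_targets:
                continue
            if site in r.bsj_seq:
                hits.append((p.primer_id, r.target_id, "bsj"))
            if site in r.linear_seq:
                hits.append((p.primer_id, r.target_id, "linear"))
    return hits


def write_references(refs: list[JunctionReference], fasta_path, index_path=None) -> None:
    """Multi-FASTA with headers targetID|bsj|offset=F and targetID|lin|offset=F,
    plus an optional TSV index."""
    with open(fasta_path, "w") as fh:
        for r in refs:
            fh.write(f">{r.target_id}|bsj|offset={r.junction_offset}\n{r.bsj_seq}\n")
            fh.write(f">{r.target_id}|lin|offset={r.junction_offset}\n{r.linear_seq}\n")
    if index_path is not None:
        with open(index_path, "w") as fh:
            fh.write(
                "target_id\tgroup_id\tjunction_offset\tflank_F\tflank_D\tclassifiable\n"
            )
            for r in refs:
                fh.write(
                    f"{r.target_id}\t{r.group_id}\t{r.junction_offset}\t"
                    f"{r.flank_F}\t{r.flank_D}\t{int(r.classifiable)}\n"
                )


def read_references(fasta_path, index_path) -> list[JunctionReference]:
    seqs: dict = {}
    with open(fasta_path) as fh:
        header = None
        chunks: list = []
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    seqs[header] = "".join(chunks)
                header = line[1:]
                chunks = []
            else:
                chunks.append(line)
        if header is not None:
            seqs[header] = "".join(chunks)
    refs = []
    with open(index_path) as fh:
        next(fh)  # header
        for line in fh:
            tid, gid, off, f, d, cls = line.rstrip("\n").split("\t")
            off = int(off)
            refs.append(
                JunctionReference(
                    target_id=tid,
                    group_id=gid,
                    bsj_seq=seqs[f"{tid}|bsj|offset={off}"],
                    linear_seq=seqs[f"{tid}|lin|offset={off}"],
                    junction_offset=off,
                    flank_F=int(f),
                    flank_D=int(d),
                    classifiable=bool(int(cls)),
                )
            )
    return refs
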