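"""Targeted junction read classification.

Each preprocessed read is matched against the panel's junction references by
seed-and-extend (exact k-mer seeds on a reference index, ungapped extension
with mismatch counting) and labelled:

- chimeric:     spans the back-splice junction of a bsj reference with at
                least min_anchor matched-region nt on each side
- linear:       likewise on a linear-junction reference
- non_junction: confined to sequence shared within an acceptor-exon group
                (the acceptor-side suffix, or a junction overlap with an
                insufficient anchor, or a 5'-flank-only hit)
- ambiguous:    best admissible hits tie (within a 1-mismatch slack) across
                distinct assignments
- unassigned:   no admissible hit

Targets that share an FSS primer have byte-identical linear references; these
are collapsed and a linear (or non-junction) read is credited to every member
target, since it is genuinely shared evidence of the one linear transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .junctions import JunctionReference
from .panel import Panel, reverse_complement

LABELS = ("chimeric", "linear", "non_junction", "ambiguous", "unassigned")


class FastqError(ValueError):
    pass


class ClassifyError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# read preprocessing
# ---------------------------------------------------------------------------

def _iter_fastq(source):
    """Yield (read_id, seq, qual) from a FASTQ path/handle or pass through an
    iterable of tuples."""
    if isinstance(source, (str, Path)):
        from Bio.SeqIO.QualityIO import FastqGeneralIterator

        with open(source) as fh:
            idx = 0
            it = FastqGeneralIterator(fh)
            while True:
                try:
                    rec = next(it)
                except StopIteration:
                    return
                except ValueError as exc:
                    raise FastqError(f"malformed FASTQ record #{idx + 1}: {exc}") from exc
                idx += 1
                yield rec[0].split()[0], rec[1], rec[2]
    else:
        for rec in source:
            if len(rec) == 2:
                yield rec[0], rec[1], "I" * len(rec[1])
            else:
                yield rec[0], rec[1], rec[2]


def preprocess_reads(
    source,
    adapter: str | None = None,
    min_quality: int = 20,
    min_read_len: int = 30,
    min_adapter_overlap: int = 5,
):
    """3' adapter removal (exact full match, else seeded suffix overlap with the
    adapter prefix), 3' quality clipping below min_quality, and a length filter.

    Returns (reads, stats): reads as a list of (id, seq, qual); stats counts
    input/kept/dropped-short reads plus adapter- and quality-trimmed tallies.
    """
    stats = {"input": 0, "kept": 0, "dropped_short": 0,
             "adapter_trimmed": 0, "quality_trimmed": 0}
    out = []
    for rid, seq, qual in _iter_fastq(source):
        stats["input"] += 1
        if len(seq) != len(qual):
            raise FastqError(f"record {rid}: sequence/quality length mismatch")
        if adapter:
            cut = seq.find(adapter)
            if cut < 0:
                cut = len(seq)
                for ov in range(min(len(adapter), len(seq)) - 1, min_adapter_overlap - 1, -1):
                    if seq.endswith(adapter[:ov]):
                        cut = len(seq) - ov
                        break
            if cut < len(seq):
                seq, qual = seq[:cut], qual[:cut]
                stats["adapter_trimmed"] += 1
        n = len(seq)
        while n > 0 and ord(qual[n - 1]) - 33 < min_quality:
            n -= 1
        if n < len(seq):
            seq, qual = seq[:n], qual[:n]
            stats["quality_trimmed"] += 1
        if len(seq) < min_read_len:
            stats["dropped_short"] += 1
            continue
        stats["kept"] += 1
        out.append((rid, seq, qual))
    return out, stats


# ---------------------------------------------------------------------------
# junction matcher
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifiedRead:
    read_id: str
    target_id: str | None  # comma-joined when evidence is shared in a group
    label: str
    mismatches: int = 0
    anchor_5: int = 0
    anchor_3: int = 0


@dataclass
class _RefRecord:
    kind: str  # 'bsj' or 'lin'
    seq: str
    junction_offset: int
    target_ids: tuple
    group_id: str


class JunctionIndex:
    """k-mer index over junction references for seed-and-extend matching."""

    def __init__(self, refs: list[JunctionReference], k: int = 12):
        if not refs:
            raise ClassifyError("empty reference set")
        self.k = k
        self.records: list[_RefRecord] = []
        lin_by_seq: dict = {}
        for r in refs:
            if not r.classifiable:
                continue
            self.records.append(
                _RefRecord("bsj", r.bsj_seq, r.junction_offset, (r.target_id,), r.group_id)
            )
            key = (r.group_id, r.linear_seq, r.junction_offset)
            lin_by_seq.setdefault(key, []).append(r.target_id)
        for (gid, seq, off), tids in lin_by_seq.items():
            self.records.append(_RefRecord("lin", seq, off, tuple(sorted(tids)), gid))
        if not self.records:
            raise ClassifyError("no classifiable reference in the reference set")
        self.kmers: dict = {}
        for ridx, rec in enumerate(self.records):
            for pos in range(len(rec.seq) - k + 1):
                self.kmers.setdefault(rec.seq[pos : pos + k], []).append((ridx, pos))

    def candidate_placements(self, read_seq: str):
        """Distinct (ref_idx, ref_start) placements where the read is fully
        contained, seeded from a handful of read k-mers."""
        k = self.k
        n = len(read_seq)
        if n < k:
            return ()
        step = max(1, (n - k) // 4) if n > k else 1
        positions = list(range(0, n - k + 1, step))
        if positions[-1] != n - k:
            positions.append(n - k)
        seen = set()
        for off in positions:
            for ridx, pos in self.kmers.get(read_seq[off : off + k], ()):
                start = pos - off
                rec = self.records[ridx]
                if start < 0 or start + n > len(rec.seq):
                    continue
                seen.add((ridx, start))
        return seen


def _count_mismatches(a: str, b: str, limit: int) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


@dataclass
class ClassifyResult:
    reads: list = field(default_factory=list)  # ClassifiedRead
    counts: pd.DataFrame | None = None  # per-target CountRecord table
    label_totals: dict = field(default_factory=dict)


def classify_reads(
    reads,
    refs: list[JunctionReference],
    min_anchor: int = 10,
    max_mismatch_rate: float = 0.05,
    ambiguity_slack: int = 1,
    unstranded: bool = False,
    sample_id: str = "sample",
    k: int = 12,
    keep_reads: bool = True,
) -> ClassifyResult:
    """Assign each read to (target, label); see module docstring for the label
    semantics. The library is stranded by construction (the FSS primer fixes
    orientation), so references are searched in one orientation unless
    unstranded=True."""
    index = JunctionIndex(refs, k=k)
    records = index.records
    totals = dict.fromkeys(LABELS, 0)
    per_target: dict = {
        r.target_id: {"n_chimeric": 0, "n_linear": 0, "n_non_junction": 0}
        for r in refs
    }
    out_reads: list[ClassifiedRead] = []

    for rec in reads:
        rid, seq = rec[0], rec[1]
        orientations = [seq] if not unstranded else [seq, reverse_complement(seq)]
        limit = int(max_mismatch_rate * len(seq))
        hits = []  # (mismatches, ref_idx, start)
        for oriented in orientations:
            for ridx, start in index.candidate_placements(oriented):
                ref = records[ridx]
                mm = _count_mismatches(
                    oriented, ref.seq[start : start + len(oriented)], limit + ambiguity_slack
                )
                if mm <= limit + ambiguity_slack:
                    hits.append((mm, ridx, start, len(oriented)))
        hits = [h for h in hits if h[0] <= limit]
        if not hits:
            totals["unassigned"] += 1
            if keep_reads:
                out_reads.append(ClassifiedRead(rid, None, "unassigned"))
            continue
        best = min(h[0] for h in hits)
        tied = [h for h in hits if h[0] <= best + ambiguity_slack]

        # canonicalize each tied hit into an assignment
        assignments = {}
        for mm, ridx, start, n in tied:
            ref = records[ridx]
            off = ref.junction_offset
            end = start + n
            a5, a3 = off - start, end - off
            if start < off < end and a5 >= min_anchor and a3 >= min_anchor:
                label = "chimeric" if ref.kind == "bsj" else "linear"
                key = (label, ref.target_ids)
            else:
                # shared-suffix / short-anchor / 5'-flank evidence: group level
                a5 = max(a5, 0) if start < off else 0
                a3 = max(a3, 0) if end > off else 0
                key = ("non_junction", (ref.group_id,))
            if key not in assignments or mm < assignments[key][0]:
                assignments[key] = (mm, a5, a3, ref)

        if len(assignments) > 1:
            totals["ambiguous"] += 1
            if keep_reads:
                out_reads.append(ClassifiedRead(rid, None, "ambiguous", best))
            continue
        (label, ids_key), (mm, a5, a3, ref) = next(iter(assignments.items()))
        totals[label] += 1
        if label in ("chimeric", "linear"):
            credited = ref.target_ids
            counter = "n_chimeric" if label == "chimeric" else "n_linear"
        else:
            credited = tuple(
                t for r2 in records if r2.group_id == ref.group_id for t in r2.target_ids
            )
            credited = tuple(sorted(set(credited)))
            counter = "n_non_junction"
        for tid in credited:
            per_target[tid][counter] += 1
        if keep_reads:
            out_reads.append(
                ClassifiedRead(rid, ",".join(credited), label, mm, a5, a3)
            )

    rows = [
        {"target_id": tid, "sample_id": sample_id, **c}
        for tid, c in sorted(per_target.items())
    ]
    counts = pd.DataFrame(rows, columns=[
        "target_id", "sample_id", "n_chimeric", "n_linear", "n_non_junction"
    ])
    totals["uniquely_assigned"] = (
        totals["chimeric"] + totals["linear"] + totals["non_junction"]
    )
    return ClassifyResult(reads=out_reads, counts=counts, label_totals=totals)


# ---------------------------------------------------------------------------
# STAR chimeric-output compatibility import
# ---------------------------------------------------------------------------

def parse_star_chimeric(path, panel: Panel, coord_tolerance: int = 5,
                        sample_id: str = "sample") -> pd.DataFrame:
    """Count chimeric junction records from a STAR Chimeric.out.junction file
    whose donor/acceptor breakpoints match a panel BSJ within coord_tolerance
    on the target's strand.

    STAR breakpoints are 1-based first intronic bases: on + the donor
    breakpoint is donor_exon.end + 1 (0-based half-open end) and the acceptor
    breakpoint is acceptor_exon.start (0-based), mirrored on -.
    """
    expected = {}
    for t in panel:
        if t.strand == "+":
            donor_bp = t.donor_exon.end + 1
            acceptor_bp = t.acceptor_exon.start
        else:
            donor_bp = t.donor_exon.start
            acceptor_bp = t.acceptor_exon.end + 1
        expected[t.target_id] = (t.chrom, t.strand, donor_bp, acceptor_bp)

    counts = dict.fromkeys(expected, 0)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chr_donorA"):
                continue
            fields = line.split("\t")
            if len(fields) < 14:
                raise ClassifyError(
                    f"{path}:{lineno}: expected >= 14 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chr_d, pos_d, strand_d, chr_a, pos_a, strand_a = fields[:6]
            try:
                pos_d, pos_a = int(pos_d), int(pos_a)
            except ValueError as exc:
                raise ClassifyError(f"{path}:{lineno}: non-integer breakpoint") from exc
            for tid, (chrom, strand, donor_bp, acceptor_bp) in expected.items():
                if (
                    chr_d == chrom
                    and chr_a == chrom
                    and strand_d == strand
                    and strand_a == strand
                    and abs(pos_d - donor_bp) <= coord_tolerance
                    and abs(pos_a - acceptor_bp) <= coord_tolerance
                ):
                    counts[tid] += 1
                    break
    rows = [
        {"target_id": tid, "sample_id": sample_id, "n_chimeric": n,
         "n_linear": 0, "n_non_junction": 0}
        for tid, n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=[
        "target_id", "sample_id", "n_chimeric", "n_linear", "n_non_junction"
    ])


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def write_per_read(reads: list, path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttarget_id\tlabel\tmismatches\tanchor_5\tanchor_3\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t{r.target_id or '.'}\t{r.label}\t{r.mismatches}\t"
                f"{r.anchor_5}\t{r.anchor_3}\n"
            )
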