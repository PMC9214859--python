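"""Targeted-library read simulator and synthetic genome/panel generators.

The simulator emulates the targeted library structure: the first-strand-
synthesis primer anchors every read's 3' end at its own 3' terminus on the
junction reference, while random-primed second-strand synthesis gives each
read a random 5' end. Per read: a target is drawn proportional to
(circular + linear abundance) x primer pool weight, the circular vs linear
template proportional to the two abundances, the 5' start uniform over a
configurable window (truncated at the reference 5' end and capped at the read
length), and iid substitution errors are applied. Quality strings are constant
Q30. All randomness flows from a mandatory seed.

The toy-genome generators are first-class fixtures: they plant multi-exon
genes with known circle structure into random sequence, so every downstream
stage can be tested against known ground truth without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .junctions import JunctionReference
from .panel import CircTarget, GenomicInterval, Panel

BASES = np.frombuffer(b"ACGT", dtype="S1")
Q30_CHAR = "?"  # phred 30, offset 33


class SimError(ValueError):
    pass


@dataclass
class SimConfig:
    """Simulation settings; abundances are relative (not normalized).

    true_circ / true_lin map target_id -> abundance; pool_weight maps
    target_id -> relative primer molarity (default 1.0). start_window is the
    inclusive range of 5' start offsets upstream of the primer 3' terminus.
    """

    true_circ: dict
    true_lin: dict
    n_reads: int
    seed: int
    pool_weight: dict = field(default_factory=dict)
    read_length: int = 300
    error_rate: float = 0.001
    start_window: tuple[int, int] = (30, 300)
    min_anchor: int = 10  # used only for truth bookkeeping

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimError("seed is required")
        if not (0 <= self.error_rate < 0.5):
            raise SimError("error_rate must be in [0, 0.5)")
        if self.n_reads < 0:
            raise SimError("n_reads must be >= 0")
        if self.read_length < 2 * self.min_anchor:
            raise SimError("read_length must be >= 2 x min_anchor")
        lo, hi = self.start_window
        if not (0 < lo <= hi):
            raise SimError("start_window must satisfy 0 < lo <= hi")
        vals = list(self.true_circ.values()) + list(self.true_lin.values())
        if any(v < 0 for v in vals):
            raise SimError("abundances must be >= 0")
        if sum(vals) == 0:
            raise SimError("abundances must not all be zero")


@dataclass
class SimTruth:
    per_target: pd.DataFrame
    per_read: pd.DataFrame


def simulate(refs: list[JunctionReference], config: SimConfig):
    """Draw reads from the junction references; returns (fastq_records, SimTruth)
    with fastq_records a list of (read_id, seq, qual)."""
    rng = np.random.default_rng(config.seed)
    ref_by_target = {r.target_id: r for r in refs}
    target_ids = sorted(
        set(config.true_circ) | set(config.true_lin),
        key=lambda t: (t not in ref_by_target, t),
    )
    weights = []
    for tid in target_ids:
        circ = config.true_circ.get(tid, 0.0)
        lin = config.true_lin.get(tid, 0.0)
        w = config.pool_weight.get(tid, 1.0)
        if circ + lin > 0 and tid not in ref_by_target:
            raise SimError(f"no junction reference for target {tid} with abundance > 0")
        weights.append((circ + lin) * w)
    probs = np.asarray(weights, dtype=float)
    probs = probs / probs.sum()

    records = []
    read_rows = []
    lo, hi = config.start_window
    if config.n_reads:
        target_draws = rng.choice(len(target_ids), size=config.n_reads, p=probs)
    else:
        target_draws = np.empty(0, dtype=int)
    for i, tix in enumerate(target_draws):
        tid = target_ids[tix]
        ref = ref_by_target[tid]
        circ = config.true_circ.get(tid, 0.0)
        lin = config.true_lin.get(tid, 0.0)
        is_circ = rng.random() < circ / (circ + lin)
        template = ref.bsj_seq if is_circ else ref.linear_seq
        u = int(rng.integers(lo, hi + 1))
        u = min(u, config.read_length, len(template))
        start = len(template) - u
        if u <= 0:
            raise SimError(f"{tid}: zero-length read window")
        seq = template[start:]
        if config.error_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype="S1").copy()
            err = rng.random(u) < config.error_rate
            n_err = int(err.sum())
            if n_err:
                # substitute with a uniformly random *different* base
                shifts = rng.integers(1, 4, size=n_err)
                idx = np.flatnonzero(err)
                base_ix = np.searchsorted(BASES, arr[idx])
                arr[idx] = BASES[(base_ix + shifts) % 4]
                seq = arr.tobytes().decode()
            n_errors = n_err
        else:
            n_errors = 0
        kind = "circ" if is_circ else "lin"
        rid = f"sim{i:07d}|{tid}|{kind}"
        records.append((rid, seq, Q30_CHAR * u))
        off = ref.junction_offset
        spans = start < off  # read 3' end is always at the reference end (> off)
        read_rows.append(
            {
                "read_id": rid,
                "target_id": tid,
                "template": kind,
                "ref_start": start,
                "read_len": u,
                "n_errors": n_errors,
                "spans_junction": spans,
                "spans_with_anchor": start <= off - config.min_anchor,
            }
        )

    per_read = pd.DataFrame(
        read_rows,
        columns=[
            "read_id", "target_id", "template", "ref_start", "read_len",
            "n_errors", "spans_junction", "spans_with_anchor",
        ],
    )
    rows = []
    for tid in target_ids:
        circ = config.true_circ.get(tid, 0.0)
        lin = config.true_lin.get(tid, 0.0)
        sub = per_read[per_read["target_id"] == tid] if len(per_read) else per_read
        n_circ = int((sub["template"] == "circ").sum()) if len(sub) else 0
        n_lin = int((sub["template"] == "lin").sum()) if len(sub) else 0
        rows.append(
            {
                "target_id": tid,
                "true_circ_abundance": circ,
                "true_lin_abundance": lin,
                "true_clr": circ / (circ + lin) if circ + lin > 0 else np.nan,
                "n_reads": n_circ + n_lin,
                "n_circ_reads": n_circ,
                "n_lin_reads": n_lin,
                "n_circ_junction": int(
                    ((sub["template"] == "circ") & sub["spans_with_anchor"]).sum()
                ) if len(sub) else 0,
                "n_lin_junction": int(
                    ((sub["template"] == "lin") & sub["spans_with_anchor"]).sum()
                ) if len(sub) else 0,
            }
        )
    per_target = pd.DataFrame(rows)
    return records, SimTruth(per_target=per_target, per_read=per_read)


def write_fastq(records, path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_truth(truth: SimTruth, per_target_path, per_read_path=None) -> None:
    truth.per_target.to_csv(per_target_path, sep="\t", index=False)
    if per_read_path is not None:
        truth.per_read.to_csv(per_read_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# synthetic genomes and panels
# ---------------------------------------------------------------------------

def _random_seq(rng, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=n, p=p).tobytes().decode()


def _plant_gene(rng, chrom_parts, cursor, exon_lens, strand, gc, intron_len=60,
                spacer_len=80):
    """Append spacer + exons (genomic order) to chrom_parts; returns
    (new_cursor, exon_intervals in transcript order)."""
    chrom_parts.append(_random_seq(rng, spacer_len, gc))
    cursor += spacer_len
    genomic_lens = exon_lens if strand == "+" else exon_lens[::-1]
    intervals = []
    for j, n in enumerate(genomic_lens):
        if j > 0:
            chrom_parts.append(_random_seq(rng, intron_len, gc))
            cursor += intron_len
        chrom_parts.append(_random_seq(rng, n, gc))
        intervals.append((cursor, cursor + n))
        cursor += n
    if strand == "-":
        intervals = intervals[::-1]  # back to transcript order
    return cursor, intervals


def make_toy_genome(n_targets: int = 2, exon_len: int = 200, seed: int = 1,
                    gc: float = 0.5):
    """Random chromosome with n_targets planted three-exon genes (upstream
    linear exon, acceptor exon, donor exon) and the matching panel; alternating
    strands; deterministic per seed. Donor and upstream flanks are re-drawn
    independently so the two junctions are always distinguishable."""
    if n_targets < 1:
        raise SimError("n_targets must be >= 1")
    rng = np.random.default_rng(seed)
    parts: list = []
    cursor = 0
    targets = []
    chrom = "chrT"
    for i in range(n_targets):
        strand = "+" if i % 2 == 0 else "-"
        cursor, (up, acc, don) = _plant_gene(
            rng, parts, cursor, [exon_len] * 3, strand, gc
        )
        gene = f"GENE{i + 1:02d}"
        targets.append(
            CircTarget(
                target_id=f"{gene}_circ1",
                host_gene=gene,
                donor_exon=GenomicInterval(chrom, *don, strand),
                acceptor_exon=GenomicInterval(chrom, *acc, strand),
                upstream_linear_exon=GenomicInterval(chrom, *up, strand),
            )
        )
    parts.append(_random_seq(rng, 80, gc))
    genome = {chrom: "".join(parts)}
    return genome, Panel(targets=targets, name=f"toy{n_targets}")


def make_synthetic_heart_panel(seed: int = 20, gc: float = 0.42):
    """Synthetic stand-in for a conserved cardiac circRNA panel: 63 circRNAs
    from 50 host genes that collapse to 52 acceptor-exon groups (37 genes with
    one circle, 11 genes with two circles sharing the 3' BSJ exon, 2 genes with
    two circles on distinct acceptor exons). Sequence content is random at a
    genome-like GC fraction; this is a structural emulation, not real loci.

    Returns (genome dict, Panel)."""
    rng = np.random.default_rng(seed)
    parts: list = []
    cursor = 0
    targets = []
    chrom = "chrS"

    def exon_lengths(n):
        return [int(rng.integers(150, 351)) for _ in range(n)]

    gene_no = 0

    def next_gene():
        nonlocal gene_no
        gene_no += 1
        return f"SYN{gene_no:02d}", "+" if gene_no % 3 else "-"

    # 37 single-circle genes: exons upstream, acceptor, donor
    for _ in range(37):
        gene, strand = next_gene()
        lens = exon_lengths(2) + [int(rng.integers(150, 351))]
        cursor, (up, acc, don) = _plant_gene(rng, parts, cursor, lens, strand, gc)
        targets.append(
            CircTarget(
                target_id=f"{gene}_circ1",
                host_gene=gene,
                donor_exon=GenomicInterval(chrom, *don, strand),
                acceptor_exon=GenomicInterval(chrom, *acc, strand),
                upstream_linear_exon=GenomicInterval(chrom, *up, strand),
            )
        )
    # 11 genes with two circles sharing the acceptor exon (one primer, 2 donors)
    for _ in range(11):
        gene, strand = next_gene()
        lens = exon_lengths(4)
        cursor, (up, acc, don1, don2) = _plant_gene(
            rng, parts, cursor, lens, strand, gc
        )
        for j, don in enumerate((don1, don2), start=1):
            targets.append(
                CircTarget(
                    target_id=f"{gene}_circ{j}",
                    host_gene=gene,
                    donor_exon=GenomicInterval(chrom, *don, strand),
                    acceptor_exon=GenomicInterval(chrom, *acc, strand),
                    upstream_linear_exon=GenomicInterval(chrom, *up, strand),
                )
            )
    # 2 genes with two circles on distinct acceptor exons (two primers)
    for _ in range(2):
        gene, strand = next_gene()
        lens = exon_lengths(5)
        cursor, (up1, acc1, don1, acc2, don2) = _plant_gene(
            rng, parts, cursor, lens, strand, gc
        )
        targets.append(
            CircTarget(
                target_id=f"{gene}_circ1",
                host_gene=gene,
                donor_exon=GenomicInterval(chrom, *don1, strand),
                acceptor_exon=GenomicInterval(chrom, *acc1, strand),
                upstream_linear_exon=GenomicInterval(chrom, *up1, strand),
            )
        )
        targets.append(
            CircTarget(
                target_id=f"{gene}_circ2",
                host_gene=gene,
                donor_exon=GenomicInterval(chrom, *don2, strand),
                acceptor_exon=GenomicInterval(chrom, *acc2, strand),
                upstream_linear_exon=GenomicInterval(chrom, *don1, strand),
            )
        )
    parts.append(_random_seq(rng, 100, gc))
    genome = {chrom: "".join(parts)}
    return genome, Panel(targets=targets, name="synthetic_heart63")


def write_genome_fasta(genome: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
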