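"""Design of first-strand-synthesis (FSS) and qPCR primers.

One FSS primer is designed per acceptor-exon group: a partial Illumina P7
adapter extension followed by a target-specific portion that is the reverse
complement of a window on the 3' BSJ exon (the RT primer anneals to the RNA).
The specific portion's Tm is tuned to the reverse-transcription reaction
temperature; the full oligo length follows the targeted library-prep kit's
length guideline. The window must sit at least a configurable distance from
the BSJ so that reads retain a classifiable junction flank.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .panel import (
    GenomeSource,
    Panel,
    group_targets_by_acceptor_exon,
    reverse_complement,
)
from .thermo import (
    QPCR_CONDITIONS,
    ThermoConditions,
    gc_fraction,
    tm,
)

# Partial Illumina P7 extension placeholder (24 nt, configurable): the kit's
# exact partial adapter is proprietary. This is the TruSeq read-2 primer core.
DEFAULT_ADAPTER = "GTGACTGGAGTTCAGACGTGTGCT"


class DesignError(RuntimeError):
    """No admissible primer for a group/region; message names the best near-miss."""


@dataclass(frozen=True)
class DesignConstraints:
    """Primer design constraints.

    Lengths are for the full oligo (adapter + specific portion); the Tm
    constraint applies to the specific portion only. Distances are measured
    from the BSJ to the primer's transcript-5'-most bound base, in nt.
    """

    full_len_optimal: tuple[int, int] = (45, 50)
    full_len_accepted: tuple[int, int] = (43, 48)
    min_bsj_distance_nt: int = 20
    preferred_bsj_distance_nt: tuple[int, int] = (30, 50)
    max_bsj_distance_nt: int = 290  # read length minus minimum anchor
    gc_target: float = 0.5

    def __post_init__(self) -> None:
        for rng in (self.full_len_optimal, self.full_len_accepted,
                    self.preferred_bsj_distance_nt):
            if rng[0] > rng[1]:
                raise ValueError(f"empty range {rng}")
        if not (self.min_bsj_distance_nt
                <= self.preferred_bsj_distance_nt[0]
                <= self.preferred_bsj_distance_nt[1]
                <= self.max_bsj_distance_nt):
            raise ValueError("require min <= preferred range <= max BSJ distance")


@dataclass
class FSSPrimer:
    primer_id: str
    group_targets: list
    adapter_seq: str
    specific_seq: str
    tm_specific_C: float
    distance_to_bsj_nt: int
    gc_fraction: float
    pool_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.pool_weight <= 0:
            raise ValueError("pool_weight must be > 0")

    @property
    def full_seq(self) -> str:
        return self.adapter_seq + self.specific_seq

    @property
    def full_length(self) -> int:
        return len(self.full_seq)


def _candidate_windows(exon_seq: str, spec_lens, constraints: DesignConstraints):
    """All (distance, length) windows on the transcript-sense acceptor exon."""
    max_dist = min(constraints.max_bsj_distance_nt, len(exon_seq))
    for dist in range(constraints.min_bsj_distance_nt, max_dist + 1):
        for n in spec_lens:
            if dist + n <= len(exon_seq):
                yield dist, exon_seq[dist : dist + n]


def score_candidate(
    window_seq: str,
    distance: int,
    cond: ThermoConditions,
    constraints: DesignConstraints,
):
    """Design objective: |Tm - reaction temp|, then |GC - target|, then
    preference for the preferred distance band, then smaller distance.
    Lower tuples are better; deterministic for reproducible tie-breaks."""
    t = tm(window_seq, cond).tm_C
    gc = gc_fraction(window_seq)
    in_preferred = (
        constraints.preferred_bsj_distance_nt[0]
        <= distance
        <= constraints.preferred_bsj_distance_nt[1]
    )
    return (
        abs(t - cond.reaction_temp_C),
        abs(gc - constraints.gc_target),
        0 if in_preferred else 1,
        distance,
    ), t, gc


def design_fss_primer(
    group_id: str,
    group_targets: list,
    acceptor_seq: str,
    cond: ThermoConditions | None = None,
    constraints: DesignConstraints | None = None,
    adapter_seq: str = DEFAULT_ADAPTER,
) -> FSSPrimer:
    """Pick the best primer window on a transcript-sense acceptor-exon sequence.

    Every start offset x specific length implied by the accepted full-oligo
    length range is scanned; the returned specific_seq is the reverse
    complement of the winning window.
    """
    cond = cond or ThermoConditions()
    constraints = constraints or DesignConstraints()
    lo = constraints.full_len_accepted[0] - len(adapter_seq)
    hi = constraints.full_len_accepted[1] - len(adapter_seq)
    if lo < 8:
        raise ValueError(
            "accepted full length minus adapter length leaves a specific portion "
            "shorter than the NN model minimum (8 nt)"
        )
    spec_lens = range(lo, hi + 1)

    best = None
    best_near_miss = None
    for dist, window in _candidate_windows(acceptor_seq, spec_lens, constraints):
        key, t, gc = score_candidate(window, dist, cond, constraints)
        if abs(t - cond.reaction_temp_C) <= cond.tm_tolerance_C:
            if best is None or key < best[0]:
                best = (key, dist, window, t, gc)
        elif best_near_miss is None or key < best_near_miss[0]:
            best_near_miss = (key, dist, window, t, gc)
    if best is None:
        if best_near_miss is None:
            raise DesignError(
                f"group {group_id}: acceptor exon ({len(acceptor_seq)} nt) hosts no "
                f"candidate window at >= {constraints.min_bsj_distance_nt} nt from "
                "the BSJ"
            )
        _, dist, window, t, gc = best_near_miss
        raise DesignError(
            f"group {group_id}: no window with Tm within "
            f"{cond.reaction_temp_C}±{cond.tm_tolerance_C} °C; best near-miss at "
            f"distance {dist} nt has Tm {t:.1f} °C (GC {gc:.2f})"
        )
    _, dist, window, t, gc = best
    return FSSPrimer(
        primer_id=f"FSS_{group_id}",
        group_targets=[tg.target_id for tg in group_targets],
        adapter_seq=adapter_seq,
        specific_seq=reverse_complement(window),
        tm_specific_C=t,
        distance_to_bsj_nt=dist,
        gc_fraction=gc,
    )


@dataclass
class PanelDesign:
    primers: list = field(default_factory=list)
    failures: dict = field(default_factory=dict)  # group_id -> message

    @property
    def ok(self) -> bool:
        return not self.failures


def design_panel(
    panel: Panel,
    genome,
    cond: ThermoConditions | None = None,
    constraints: DesignConstraints | None = None,
    adapter_seq: str = DEFAULT_ADAPTER,
    pool_weights: dict | None = None,
) -> PanelDesign:
    """Design one FSS primer per acceptor-exon group of the panel.

    pool_weights maps primer_id or any member target_id to a relative molarity
    (e.g. 0.01 to down-weight one very abundant target to 1%); design failures
    are collected per group and do not abort remaining groups.
    """
    src = GenomeSource(genome)
    groups = group_targets_by_acceptor_exon(panel)
    pool_weights = pool_weights or {}
    out = PanelDesign()
    for key, targets in groups.items():
        group_id = "_".join(sorted(t.target_id for t in targets))
        acceptor_seq = src.transcript_seq(targets[0].acceptor_exon)
        try:
            primer = design_fss_primer(
                group_id, targets, acceptor_seq, cond, constraints, adapter_seq
            )
        except DesignError as exc:
            out.failures[group_id] = str(exc)
            continue
        weight = pool_weights.get(primer.primer_id)
        if weight is None:
            for tid in primer.group_targets:
                if tid in pool_weights:
                    weight = pool_weights[tid]
                    break
        if weight is not None:
            primer = replace(primer, pool_weight=float(weight))
        out.primers.append(primer)
    return out


def design_qpcr_primer(
    region: str,
    cond: ThermoConditions | None = None,
    length: int = 20,
    max_length: int = 30,
    tm_range: tuple[float, float] = (55.0, 57.0),
    gc_target: float = 0.5,
) -> dict:
    """Pick a qPCR primer on a transcript-sense region: a 20-mer closest to the
    GC target with Tm in range; length grows (low-GC regions) until the Tm
    constraint is met, up to max_length."""
    cond = cond or QPCR_CONDITIONS
    region = region.strip().upper()
    if len(region) < length:
        raise DesignError(f"region ({len(region)} nt) shorter than primer length")
    best_near = None
    for n in range(length, max_length + 1):
        best = None
        for start in range(0, len(region) - n + 1):
            window = region[start : start + n]
            t = tm(window, cond).tm_C
            gc = gc_fraction(window)
            key = (abs(gc - gc_target), start)
            if tm_range[0] <= t <= tm_range[1]:
                if best is None or key < best[0]:
                    best = (key, start, window, t, gc)
            near_key = (min(abs(t - tm_range[0]), abs(t - tm_range[1])), key)
            if best_near is None or near_key < best_near[0]:
                best_near = (near_key, n, t, gc)
        if best is not None:
            _, start, window, t, gc = best
            return {
                "seq": window,
                "start": start,
                "length": n,
                "tm_C": t,
                "gc_fraction": gc,
            }
    assert best_near is not None
    _, n, t, gc = best_near
    raise DesignError(
        f"no primer up to {max_length} nt reaches Tm {tm_range[0]}-{tm_range[1]} °C; "
        f"best near-miss ({n} nt) has Tm {t:.1f} °C (GC {gc:.2f})"
    )


def write_primers_tsv(primers: list, path) -> None:
    cols = [
        "primer_id", "group_targets", "adapter_seq", "specific_seq", "full_seq",
        "full_length", "tm_specific_C", "distance_to_bsj_nt", "gc_fraction",
        "pool_weight",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for p in primers:
            fh.write(
                "\t".join(
                    [
                        p.primer_id,
                        ",".join(p.group_targets),
                        p.adapter_seq,
                        p.specific_seq,
                        p.full_seq,
                        str(p.full_length),
                        f"{p.tm_specific_C:.2f}",
                        str(p.distance_to_bsj_nt),
                        f"{p.gc_fraction:.3f}",
                        f"{p.pool_weight:g}",
                    ]
                )
                + "\n"
            )


def write_pool_manifest(primers: list, path) -> None:
    with open(path, "w") as fh:
        fh.write("primer_id\tpool_weight\n")
        for p in primers:
            fh.write(f"{p.primer_id}\t{p.pool_weight:g}\n")


def write_primers_fasta(primers: list, path) -> None:
    with open(path, "w") as fh:
        for p in primers:
            fh.write(f">{p.primer_id}\n{p.full_seq}\n")
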