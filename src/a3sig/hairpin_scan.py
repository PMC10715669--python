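"""Inverted-repeat (stem-loop) scanning and hairpin-loop mutation rates.

A hairpin here is a perfect Watson-Crick inverted repeat: a 5' arm, a
single-stranded loop of 3-11 nt, and a 3' arm that is the reverse complement
of the 5' arm, with a minimum stem of 6 bp.  Only the maximal stem for each
loop placement is reported (capped at ``max_stem``); no mismatches, bulges or
G.T wobble pairs are allowed, and N never participates in a stem or loop.

Loop bases form the single-stranded compartment used for rate comparisons;
stem bases count toward the non-hairpin denominator, so
``loop_bp + nonhairpin_bp`` equals the assembled genome length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .variant_io import OrientedContext, ReferenceSequence

_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class Hairpin:
    contig: str
    arm5_start: int
    arm5_end: int
    loop_start: int
    loop_end: int
    arm3_start: int
    arm3_end: int
    stem_len: int
    loop_len: int


@dataclass
class LoopMask:
    """Merged, disjoint loop intervals per contig with total base counts."""

    intervals: dict[str, list[tuple[int, int]]]
    loop_bp: int
    nonhairpin_bp: int

    def contains(self, contig: str, pos0: int) -> bool:
        ivals = self.intervals.get(contig)
        if not ivals:
            return False
        starts = [s for s, _ in ivals]
        import bisect

        i = bisect.bisect_right(starts, pos0) - 1
        return i >= 0 and ivals[i][0] <= pos0 < ivals[i][1]


def find_hairpins(
    genome: ReferenceSequence,
    min_stem: int = 6,
    max_stem: int = 15,
    loop_min: int = 3,
    loop_max: int = 11,
) -> list[Hairpin]:
    """Scan every contig for perfect inverted repeats.

    For each loop placement (start position and length in
    [``loop_min``, ``loop_max``]) the stem is extended outward base by base
    while the flanks are Watson-Crick complementary; a hairpin is reported
    when the maximal extension reaches ``min_stem``, with the stem capped at
    ``max_stem``.
    """
    if loop_min < 1:
        raise ValueError("loop_min must be >= 1")
    if min_stem < 1:
        raise ValueError("min_stem must be >= 1")
    if loop_min > loop_max:
        raise ValueError("loop_min > loop_max")
    out: list[Hairpin] = []
    for contig, seq in genome.contigs.items():
        n = len(seq)
        code = np.frombuffer(seq.encode(), dtype=np.uint8)
        comp = np.zeros(256, dtype=np.uint8)
        for a, b in _PAIR.items():
            comp[ord(a)] = ord(b)
        comp_code = comp[code]  # complement; N maps to 0, never equal to a base
        has_n = code == ord("N")
        n_cum = np.concatenate(([0], np.cumsum(has_n)))
        for loop_len in range(loop_min, loop_max + 1):
            # candidate loop starts: need at least min_stem on both sides
            starts = np.arange(min_stem, n - loop_len - min_stem + 1)
            if starts.size == 0:
                continue
            # exclude loops containing N
            loop_n = n_cum[starts + loop_len] - n_cum[starts] > 0
            alive = ~loop_n
            stem = np.zeros(starts.size, dtype=np.int64)
            for k in range(max_stem):
                left = starts - 1 - k
                right = starts + loop_len + k
                ok = alive & (left >= 0) & (right < n)
                idx = np.where(ok)[0]
                if idx.size == 0:
                    break
                match = code[left[idx]] == comp_code[right[idx]]
                # N never pairs: comp maps N->0, code[N]=ord('N') != 0 for
                # partner N; also forbid left N explicitly
                match &= code[left[idx]] != ord("N")
                stem_idx = idx[match]
                stem[stem_idx] += 1
                dead = idx[~match]
                alive[dead] = False
            for i in np.where(stem >= min_stem)[0]:
                s = int(starts[i])
                sl = int(min(stem[i], max_stem))
                out.append(
                    Hairpin(
                        contig=contig,
                        arm5_start=s - sl,
                        arm5_end=s,
                        loop_start=s,
                        loop_end=s + loop_len,
                        arm3_start=s + loop_len,
                        arm3_end=s + loop_len + sl,
                        stem_len=sl,
                        loop_len=loop_len,
                    )
                )
    return out


def build_loop_mask(
    hairpins: Iterable[Hairpin], genome: ReferenceSequence
) -> LoopMask:
    """Union of hairpin loop intervals; stems count as non-hairpin."""
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for hp in hairpins:
        by_contig.setdefault(hp.contig, []).append((hp.loop_start, hp.loop_end))
    merged: dict[str, list[tuple[int, int]]] = {}
    loop_bp = 0
    for contig, ivals in by_contig.items():
        ivals.sort()
        out: list[list[int]] = [list(ivals[0])]
        for s, e in ivals[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[contig] = [(s, e) for s, e in out]
        loop_bp += sum(e - s for s, e in out)
    total = genome.total_bp
    return LoopMask(intervals=merged, loop_bp=loop_bp, nonhairpin_bp=total - loop_bp)


def mask_from_intervals(
    intervals: Iterable[tuple[str, int, int]], genome: ReferenceSequence
) -> LoopMask:
    """LoopMask from explicit (contig, start, end) loop intervals (0-based)."""
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, s, e in intervals:
        by_contig.setdefault(contig, []).append((int(s), int(e)))
    merged: dict[str, list[tuple[int, int]]] = {}
    loop_bp = 0
    for contig, ivals in by_contig.items():
        ivals.sort()
        out: list[list[int]] = [list(ivals[0])]
        for s, e in ivals[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[contig] = [(s, e) for s, e in out]
        loop_bp += sum(e - s for s, e in out)
    return LoopMask(merged, loop_bp, genome.total_bp - loop_bp)


@dataclass
class LoopRateResult:
    per_clone: "object"  # pandas DataFrame
    tests: dict[str, float | None]


def loop_mutation_rates(
    contexts: Iterable[OrientedContext],
    mask: LoopMask,
    conditions: Mapping[str, str],
    loop_bp: float | None = None,
    nonhairpin_bp: float | None = None,
) -> LoopRateResult:
    """Per-clone loop vs non-hairpin rates of APOBEC3 signature TCW mutations.

    Each signature mutation is classified by loop-mask membership of its
    position; rates are per Mbp of the respective compartment.  Welch t-tests
    (two-sided) compare loop vs non-hairpin rates within each condition and
    loop rates between conditions.  ``loop_bp``/``nonhairpin_bp`` can override
    the mask's denominators (e.g. to use published genome-wide estimates).
    """
    import pandas as pd

    lbp = float(loop_bp if loop_bp is not None else mask.loop_bp)
    nbp = float(nonhairpin_bp if nonhairpin_bp is not None else mask.nonhairpin_bp)
    counts: dict[str, list[int]] = {}
    for ctx in contexts:
        if not ctx.is_apobec_signature:
            continue
        sid = ctx.mutation.sample_id
        if sid not in conditions:
            raise KeyError(f"clone {sid!r} has no condition label")
        d = counts.setdefault(sid, [0, 0])
        if mask.contains(ctx.mutation.chrom, ctx.mutation.pos - 1):
            d[0] += 1
        else:
            d[1] += 1
    rows = []
    for sid, (n_loop, n_non) in counts.items():
        rows.append(
            {
                "sample_id": sid,
                "condition": conditions[sid],
                "n_loop_TCW": n_loop,
                "n_nonhairpin_TCW": n_non,
                "rate_loop": n_loop / (lbp / 1e6) if lbp > 0 else float("nan"),
                "rate_nonhairpin": n_non / (nbp / 1e6) if nbp > 0 else float("nan"),
            }
        )
    df = pd.DataFrame(rows)
    tests: dict[str, float | None] = {}
    if not df.empty:
        for cond, grp in df.groupby("condition"):
            tests[f"{cond}:loop_vs_nonhairpin"] = _welch(
                grp["rate_loop"], grp["rate_nonhairpin"]
            )
        conds = sorted(df["condition"].unique())
        for i, a in enumerate(conds):
            for b in conds[i + 1 :]:
                tests[f"{a}_vs_{b}:loop"] = _welch(
                    df.loc[df.condition == a, "rate_loop"],
                    df.loc[df.condition == b, "rate_loop"],
                )
    return LoopRateResult(per_clone=df, tests=tests)


def _welch(a, b) -> float | None:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        return None
    if np.all(a == 0) and np.all(b == 0):
        return None  # not computable on all-zero groups
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)


def hairpins_to_bed(hairpins: Sequence[Hairpin]) -> "object":
    """BED6+ table: full hairpin span, stem length, and loop interval columns."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "contig": hp.contig,
                "start": hp.arm5_start,
                "end": hp.arm3_end,
                "name": f"hp_{hp.contig}_{hp.loop_start}_{hp.loop_len}",
                "stem_len": hp.stem_len,
                "strand": ".",
                "loop_start": hp.loop_start,
                "loop_end": hp.loop_end,
            }
            for hp in hairpins
        ]
    )
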