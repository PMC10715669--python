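"""Synthetic genomes and mutation catalogs with full truth labels.

The generator emulates the statistical structure the analysis assumes:

* per-clone SBS totals drawn from condition-level normal count models
  (A3A 3494/1358, A3B 2334/278, control 1729/388; truncated at 0, rounded);
* APOBEC mutations placed on TCW cytosines of either strand, as C>T/C>G,
  with a tunable -2 pyrimidine probability (A3A-mode 0.727, A3B-mode 0.472)
  and +1 A/T balance (A3A 0.483/0.363, A3B 0.339/0.412, renormalized within
  W) -- so the configured -2 pyrimidine probability is exactly the expected
  YTCW fraction of the emitted APOBEC mutations;
* a background over the six pyrimidine substitution classes with a
  configurable C>A excess (a ganciclovir-like "signature B");
* strand-coordinated kataegis runs (2-5 members, spans within 10 kb);
* an APOBEC rate multiplier inside planted hairpin loops.

Everything is deterministic under the master seed; positions are unique
within a clone and emitted ref alleles always match the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variant_io import MutationRecord, ReferenceSequence, revcomp

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class MotifModel:
    """APOBEC target-site preferences within the TCW motif."""

    p_minus2_pyrimidine: float
    p_plus1_A: float
    p_plus1_T: float
    p_c_to_t: float = 0.6  # C>T vs C>G split within the APOBEC channel

    def __post_init__(self) -> None:
        for p in (self.p_minus2_pyrimidine, self.p_plus1_A, self.p_plus1_T, self.p_c_to_t):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def p_plus1_A_given_W(self) -> float:
        return self.p_plus1_A / (self.p_plus1_A + self.p_plus1_T)


#: Motif models measured for each enzyme (YTCW 72.7% / 47.2%; +1 A vs T
#: 48.3%/36.3% and 33.9%/41.2%).
A3A_MOTIF = MotifModel(0.727, 0.483, 0.363)
A3B_MOTIF = MotifModel(0.472, 0.339, 0.412)


@dataclass
class ConditionModel:
    count_mean: float
    count_sd: float
    apobec_fraction: float
    motif: MotifModel | None  # None for non-APOBEC conditions
    kataegis_events: float = 0.0  # expected events per clone (Poisson)


PYRIMIDINE_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


@dataclass
class SimulationConfig:
    """Study conditions for a simulated mutagenesis cohort.

    Count models come from the measured per-clone SBS totals; APOBEC
    fractions are estimates from pooled tallies (A3A ~6070 of ~21,000 SBS,
    A3B ~1528 of ~11,700, controls none).
    """

    seed: int = 1
    genome_len: int = 1_000_000
    gc: float = 0.4
    n_clones: Mapping[str, int] = field(
        default_factory=lambda: {"A3A": 6, "A3B": 5, "control": 6}
    )
    conditions: Mapping[str, ConditionModel] = field(
        default_factory=lambda: {
            "A3A": ConditionModel(3494.0, 1358.0, 0.29, A3A_MOTIF, kataegis_events=0.7),
            "A3B": ConditionModel(2334.0, 278.0, 0.13, A3B_MOTIF, kataegis_events=0.2),
            "control": ConditionModel(1729.0, 388.0, 0.0, None),
        }
    )
    # background class weights: uniform over six classes plus a C>A excess,
    # or an explicit weight vector over PYRIMIDINE_CLASSES
    background_c_to_a_excess: float = 1.0
    background_class_weights: Sequence[float] | None = None
    kataegis_members: tuple[int, int] = (2, 5)
    kataegis_span: tuple[float, float] = (500.0, 9500.0)
    # hairpin planting
    n_hairpins: int = 0
    hairpin_stem: int = 8
    hairpin_loop: int = 5
    loop_rate_multiplier: float = 1.0

    def background_weights(self) -> np.ndarray:
        if self.background_class_weights is not None:
            w = np.asarray(self.background_class_weights, dtype=float)
            if w.size != len(PYRIMIDINE_CLASSES) or np.any(w < 0) or w.sum() == 0:
                raise ValueError("invalid background class weights")
        else:
            w = np.ones(len(PYRIMIDINE_CLASSES))
            w[PYRIMIDINE_CLASSES.index("C>A")] += self.background_c_to_a_excess
        return w / w.sum()


def make_genome(length: int, gc: float, seed: int) -> ReferenceSequence:
    """I.i.d. random genome with P(G) = P(C) = gc/2, single contig 'chr1'."""
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=probs)
    return ReferenceSequence({"chr1": arr.tobytes().decode()})


def plant_hairpins(
    genome: ReferenceSequence,
    n: int,
    stem: int = 8,
    loop: int = 5,
    seed: int = 0,
    min_gap: int = 50,
) -> tuple[ReferenceSequence, pd.DataFrame]:
    """Overwrite ``n`` non-overlapping sites with perfect inverted repeats.

    Guard bases on both sides of each placement are set non-complementary so
    the planted stem cannot extend by chance, making recovered coordinates
    exact.  Returns the modified genome and a truth table (BED-like, 0-based
    half-open loop and arm intervals).
    """
    rng = np.random.default_rng(seed)
    if n == 0:
        return genome, pd.DataFrame(
            columns=["contig", "arm5_start", "loop_start", "loop_end", "arm3_end", "stem", "loop"]
        )
    site = 2 + stem + loop + stem + 2  # guards + arms + loop
    contig = max(genome.contigs, key=lambda c: genome.lengths[c])
    seq = np.frombuffer(genome.contigs[contig].encode(), dtype=np.uint8).copy()
    if len(seq) < n * (site + min_gap):
        raise ValueError("genome too short for requested hairpin placements")
    # non-overlapping placements with a minimum gap
    spacing = len(seq) // n
    starts = []
    for i in range(n):
        lo = i * spacing
        hi = min((i + 1) * spacing, len(seq)) - site
        if hi <= lo:
            raise ValueError("genome too short for requested hairpin placements")
        starts.append(int(rng.integers(lo, hi)))
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    rows = []
    for s in starts:
        arm5 = rng.choice(bases, size=stem)
        loop_seq = rng.choice(bases, size=loop)
        arm3 = np.frombuffer(
            revcomp(arm5.tobytes().decode()).encode(), dtype=np.uint8
        )
        a5 = s + 2
        ls = a5 + stem
        le = ls + loop
        a3e = le + stem
        seq[a5:ls] = arm5
        seq[ls:le] = loop_seq
        seq[le:a3e] = arm3
        # guards: make flank pairs non-complementary to stop stem extension
        left_guard = seq[a5 - 1]
        partner = ord(_COMP[chr(seq[a3e])]) if a3e < len(seq) else None
        if partner is not None and left_guard == partner:
            choices = [b for b in b"ACGT" if b != partner]
            seq[a5 - 1] = int(rng.choice(choices))
        rows.append(
            {
                "contig": contig,
                "arm5_start": a5,
                "loop_start": ls,
                "loop_end": le,
                "arm3_end": a3e,
                "stem": stem,
                "loop": loop,
            }
        )
    contigs = dict(genome.contigs)
    contigs[contig] = seq.tobytes().decode()
    return ReferenceSequence(contigs), pd.DataFrame(rows)


class SiteIndex:
    """Positions of TCW cytosines (both strands) and background-eligible bases.

    Categories are keyed by (-2 class 'Y'/'R', +1 base 'A'/'T') in oriented
    (pyrimidine) coordinates.  Positions are 0-based per contig, restricted
    so the full pentanucleotide window fits inside the contig.
    """

    def __init__(self, genome: ReferenceSequence):
        self.genome = genome
        self.tcw: dict[str, dict[tuple[str, str], np.ndarray]] = {}
        self.tcw_strand: dict[str, dict[str, np.ndarray]] = {}
        self.pyr: dict[str, dict[str, np.ndarray]] = {}
        for contig, seq in genome.contigs.items():
            code = np.frombuffer(seq.encode(), dtype=np.uint8)
            n = len(code)
            A, C, G, T = (ord(x) for x in "ACGT")
            valid = np.zeros(n, dtype=bool)
            valid[2 : n - 2] = True
            is_t = code == T
            is_c = code == C
            is_g = code == G
            is_a = code == A
            w_fwd = is_a | is_t
            # forward strand: T C W at i-1, i, i+1
            fwd = valid & is_c
            fwd[2:-2] &= is_t[1:-3] & w_fwd[3:-1]
            # reverse strand: reference reads W' G A at i-1, i, i+1
            rev = valid & is_g
            rev[2:-2] &= is_a[3:-1] & w_fwd[1:-3]
            cat: dict[tuple[str, str], list[np.ndarray]] = {
                (y, p1): [] for y in "YR" for p1 in "AT"
            }
            fidx = np.where(fwd)[0]
            if fidx.size:
                m2_y = is_c[fidx - 2] | is_t[fidx - 2]
                p1_a = is_a[fidx + 1]
                for y_flag, y in ((True, "Y"), (False, "R")):
                    for a_flag, p1 in ((True, "A"), (False, "T")):
                        cat[(y, p1)].append(fidx[(m2_y == y_flag) & (p1_a == a_flag)])
            ridx = np.where(rev)[0]
            if ridx.size:
                # oriented -2 base = complement of code[i+2]; pyrimidine iff
                # reference base at i+2 is A or G
                m2_y = is_a[ridx + 2] | is_g[ridx + 2]
                # oriented +1 base = complement of code[i-1]
                p1_a = is_t[ridx - 1]
                for y_flag, y in ((True, "Y"), (False, "R")):
                    for a_flag, p1 in ((True, "A"), (False, "T")):
                        cat[(y, p1)].append(ridx[(m2_y == y_flag) & (p1_a == a_flag)])
            self.tcw[contig] = {
                k: np.sort(np.concatenate(v)) if v else np.empty(0, dtype=np.int64)
                for k, v in cat.items()
            }
            self.tcw_strand[contig] = {
                "+": fidx,
                "-": ridx,
            }
            pos = np.where(valid)[0]
            self.pyr[contig] = {
                "C": pos[(is_c | is_g)[pos]],
                "T": pos[(is_t | is_a)[pos]],
            }


def draw_clone_count(rng: np.random.Generator, model: ConditionModel) -> int:
    """Per-clone SBS total: normal(mean, sd) truncated at 0 and rounded."""
    return int(round(max(0.0, rng.normal(model.count_mean, model.count_sd))))


@dataclass
class SimTruth:
    """Per-mutation truth labels aligned with the emitted records."""

    frame: pd.DataFrame  # origin, kataegis_id, in_loop


def _sample_without_replacement(
    rng: np.random.Generator,
    positions: np.ndarray,
    k: int,
    used: set[int],
    channel: str = "",
) -> np.ndarray:
    """Uniform sample of k unused positions; errors naming the channel if short."""
    if k == 0:
        return np.empty(0, dtype=np.int64)
    if used:
        free = positions[~np.isin(positions, np.fromiter(used, dtype=np.int64))]
    else:
        free = positions
    if free.size < k:
        raise ValueError(f"insufficient eligible sites in channel {channel or '?'}")
    return rng.choice(free, size=k, replace=False)


def _oriented_alt(ref_base: str, oriented_alt: str) -> str:
    """Reference-strand alt allele for an oriented pyrimidine substitution."""
    return oriented_alt if ref_base in "CT" else _COMP[oriented_alt]


def simulate_clone(
    genome: ReferenceSequence,
    config: SimulationConfig,
    condition: str,
    seed: int,
    sample_id: str | None = None,
    loop_intervals: pd.DataFrame | None = None,
    n_mutations: int | None = None,
    site_index: SiteIndex | None = None,
) -> tuple[list[MutationRecord], SimTruth]:
    """Simulate one clone's SBS catalog under a condition's models.

    ``n_mutations`` overrides the condition count model (useful for large
    calibration catalogs); ``loop_intervals`` is the truth table from
    :func:`plant_hairpins` and activates the loop rate multiplier.
    """
    if condition not in config.conditions:
        raise KeyError(f"unknown condition {condition!r}")
    model = config.conditions[condition]
    rng = np.random.default_rng(seed)
    sid = sample_id or f"{condition}_clone"
    if site_index is None:
        site_index = SiteIndex(genome)

    n_total = (
        int(n_mutations) if n_mutations is not None else draw_clone_count(rng, model)
    )
    n_apobec = int(round(model.apobec_fraction * n_total))
    n_background = n_total - n_apobec

    # loop membership lookup (single pass arrays per contig)
    loop_lookup: dict[str, np.ndarray] = {}
    if loop_intervals is not None and len(loop_intervals):
        for contig, grp in loop_intervals.groupby("contig"):
            mask = np.zeros(genome.lengths[contig], dtype=bool)
            for _, r in grp.iterrows():
                mask[int(r["loop_start"]) : int(r["loop_end"])] = True
            loop_lookup[contig] = mask

    def in_loop(contig: str, pos0: int) -> bool:
        m = loop_lookup.get(contig)
        return bool(m[pos0]) if m is not None else False

    used: dict[str, set[int]] = {c: set() for c in genome.contigs}
    records: list[MutationRecord] = []
    truth_rows: list[dict] = []

    def emit(contig: str, pos0: int, ref: str, alt: str, origin: str, kid: int) -> None:
        used[contig].add(pos0)
        records.append(
            MutationRecord(sid, condition, contig, pos0 + 1, ref, alt)
        )
        truth_rows.append(
            {
                "sample_id": sid,
                "chrom": contig,
                "pos": pos0 + 1,
                "origin": origin,
                "kataegis_id": kid,
                "in_loop": in_loop(contig, pos0),
            }
        )

    # --- kataegis runs (count toward the APOBEC tally) ---
    n_events = rng.poisson(model.kataegis_events) if model.apobec_fraction > 0 else 0
    placed_members = 0
    for event_id in range(n_events):
        if placed_members >= n_apobec:
            break
        k = int(rng.integers(config.kataegis_members[0], config.kataegis_members[1] + 1))
        k = min(k, n_apobec - placed_members)
        if k < 2:
            break
        span = float(rng.uniform(*config.kataegis_span))
        placed = False
        for _ in range(200):  # rejection sampling for a window with enough sites
            contig = str(rng.choice(list(genome.contigs)))
            strand = "+" if rng.random() < 0.5 else "-"
            sites = site_index.tcw_strand[contig][strand]
            if sites.size == 0:
                continue
            anchor = int(sites[rng.integers(sites.size)])
            lo, hi = np.searchsorted(sites, [anchor, anchor + span])
            window_sites = [
                int(p) for p in sites[lo:hi] if int(p) not in used[contig]
            ]
            if len(window_sites) < k:
                continue
            chosen = sorted(
                int(x) for x in rng.choice(window_sites, size=k, replace=False)
            )
            seq = genome.contigs[contig]
            for pos0 in chosen:
                o_alt = "T" if rng.random() < model.motif.p_c_to_t else "G"
                emit(contig, pos0, seq[pos0], _oriented_alt(seq[pos0], o_alt), "apobec", event_id)
            placed_members += k
            placed = True
            break
        if not placed:
            raise ValueError("could not place a kataegis run: too few TCW sites")

    # --- dispersed APOBEC mutations by motif category ---
    # The loop rate multiplier acts on the per-base rate: the dispersed count
    # is split between the loop and non-hairpin compartments with probability
    # proportional to (multiplier * loop_bp) vs nonhairpin_bp, then sites are
    # drawn uniformly within each compartment, so the expected per-Mbp rate
    # ratio equals the configured multiplier exactly.
    n_dispersed = n_apobec - placed_members
    if n_dispersed > 0:
        if model.motif is None:
            raise ValueError(f"condition {condition!r} has apobec_fraction > 0 but no motif model")
        m = model.motif
        p_y = m.p_minus2_pyrimidine
        p_a = m.p_plus1_A_given_W
        cat_probs = {
            ("Y", "A"): p_y * p_a,
            ("Y", "T"): p_y * (1 - p_a),
            ("R", "A"): (1 - p_y) * p_a,
            ("R", "T"): (1 - p_y) * (1 - p_a),
        }
        cats = list(cat_probs)
        loop_bp = sum(int(mk.sum()) for mk in loop_lookup.values())
        split_loops = config.loop_rate_multiplier != 1.0 and loop_bp > 0
        if split_loops:
            nonhairpin_bp = genome.total_bp - loop_bp
            p_loop = (config.loop_rate_multiplier * loop_bp) / (
                config.loop_rate_multiplier * loop_bp + nonhairpin_bp
            )
            n_loop_muts = int(rng.binomial(n_dispersed, p_loop))
            compartments = [("loop", n_loop_muts), ("nonhairpin", n_dispersed - n_loop_muts)]
        else:
            compartments = [("all", n_dispersed)]
        for comp_name, n_comp in compartments:
            if n_comp == 0:
                continue
            n_by_cat = rng.multinomial(n_comp, [cat_probs[c] for c in cats])
            for cat, n_cat in zip(cats, n_by_cat):
                if n_cat == 0:
                    continue
                pools = []
                for contig in genome.contigs:
                    pos = site_index.tcw[contig][cat]
                    if comp_name != "all":
                        lm = loop_lookup.get(contig)
                        in_lp = lm[pos] if lm is not None else np.zeros(pos.size, bool)
                        pos = pos[in_lp] if comp_name == "loop" else pos[~in_lp]
                    if pos.size:
                        pools.append((contig, pos))
                sizes = np.array([p[1].size for p in pools], dtype=float)
                if sizes.sum() < n_cat:
                    raise ValueError(
                        f"insufficient eligible sites in channel {cat[0]}TC{cat[1]} ({comp_name})"
                    )
                alloc = rng.multinomial(int(n_cat), sizes / sizes.sum())
                # rebalance any contig allocated more than it holds
                for _ in range(10):
                    over = [i for i, (n_c, s) in enumerate(zip(alloc, sizes)) if n_c > s]
                    if not over:
                        break
                    excess = int(sum(alloc[i] - sizes[i] for i in over))
                    for i in over:
                        alloc[i] = int(sizes[i])
                    room = [i for i, (n_c, s) in enumerate(zip(alloc, sizes)) if n_c < s]
                    for i in room:
                        take = min(excess, int(sizes[i] - alloc[i]))
                        alloc[i] += take
                        excess -= take
                        if excess == 0:
                            break
                for (contig, pos), n_c in zip(pools, alloc):
                    if n_c == 0:
                        continue
                    chosen = _sample_without_replacement(
                        rng, pos, int(n_c), used[contig], f"{cat[0]}TC{cat[1]}"
                    )
                    seq = genome.contigs[contig]
                    for pos0 in sorted(int(x) for x in chosen):
                        o_alt = "T" if rng.random() < m.p_c_to_t else "G"
                        emit(
                            contig, pos0, seq[pos0], _oriented_alt(seq[pos0], o_alt), "apobec", -1
                        )

    # --- background mutations ---
    if n_background > 0:
        bw = config.background_weights()
        class_draws = rng.multinomial(n_background, bw)
        for cls, n_cls in zip(PYRIMIDINE_CLASSES, class_draws):
            if n_cls == 0:
                continue
            o_ref, o_alt = cls[0], cls[2]
            remaining = int(n_cls)
            pools = [
                (contig, site_index.pyr[contig][o_ref])
                for contig in genome.contigs
                if site_index.pyr[contig][o_ref].size
            ]
            sizes = np.array([p[1].size for p in pools], dtype=float)
            alloc = rng.multinomial(remaining, sizes / sizes.sum())
            for (contig, pos), n_c in zip(pools, alloc):
                if n_c == 0:
                    continue
                chosen = _sample_without_replacement(
                    rng, pos, int(n_c), used[contig], cls
                )
                seq = genome.contigs[contig]
                for pos0 in sorted(int(x) for x in chosen):
                    emit(
                        contig,
                        pos0,
                        seq[pos0],
                        _oriented_alt(seq[pos0], o_alt),
                        "background",
                        -1,
                    )

    truth = SimTruth(pd.DataFrame(truth_rows))
    return records, truth


def _child_seed(master_seed: int, label: str) -> int:
    """Deterministic per-clone seed below 2**31."""
    import zlib

    return int(
        (np.random.SeedSequence([master_seed, zlib.crc32(label.encode())]).generate_state(1)[0])
        % (2**31)
    )


def simulate_cohort(
    config: SimulationConfig,
    genome: ReferenceSequence | None = None,
    loop_intervals: pd.DataFrame | None = None,
) -> tuple[dict[str, list[MutationRecord]], dict[str, SimTruth], pd.DataFrame]:
    """Simulate every clone of every requested condition.

    Returns (catalogs by clone, truth by clone, manifest).  Clone seeds are
    derived deterministically from the master seed, so a fixed config gives
    byte-identical catalogs.
    """
    for cond in config.n_clones:
        if cond not in config.conditions:
            raise KeyError(f"unknown condition {cond!r}")
    if genome is None:
        genome = make_genome(config.genome_len, config.gc, config.seed)
        if config.n_hairpins:
            genome, loop_intervals = plant_hairpins(
                genome,
                config.n_hairpins,
                config.hairpin_stem,
                config.hairpin_loop,
                seed=_child_seed(config.seed, "hairpins"),
            )
    site_index = SiteIndex(genome)
    catalogs: dict[str, list[MutationRecord]] = {}
    truths: dict[str, SimTruth] = {}
    manifest_rows = []
    for cond, n in config.n_clones.items():
        for i in range(1, n + 1):
            clone = f"{cond}_{i:02d}"
            seed = _child_seed(config.seed, clone)
            recs, truth = simulate_clone(
                genome,
                config,
                cond,
                seed,
                sample_id=clone,
                loop_intervals=loop_intervals,
                site_index=site_index,
            )
            catalogs[clone] = recs
            truths[clone] = truth
            manifest_rows.append(
                {"clone": clone, "condition": cond, "seed": seed, "n_mutations": len(recs)}
            )
    return catalogs, truths, pd.DataFrame(manifest_rows)
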