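"""Spectra, motif fractions, TCW enrichment scores, and cohort summaries.

The APOBEC3 signature is C>T and C>G substitution at TCW motifs (W = A/T;
COSMIC SBS2/SBS13).  The enrichment score compares the TCW fraction among a
sample's cytosine mutations with the TCW fraction among cytosines in the
local sequence context (+/- ``window`` nt around each mutated cytosine):

    E = (M_TCW * C_C) / (M_C * C_TCW)

with a one-sided Fisher exact test on [[M_TCW, C_TCW], [M_C-M_TCW, C_C-C_TCW]]
and Benjamini-Hochberg correction across samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variant_io import OrientedContext, ReferenceSequence

PYRIMIDINE_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"

#: 96 trinucleotide channels, alphabetical flanks within each class.
TRI_CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{cls}]{three}"
    for cls in PYRIMIDINE_CLASSES
    for five in BASES
    for three in BASES
)

#: 48 pentanucleotide C>T channels N T[C>T] H N (H = A/C/T; TCG excluded).
PENTA_CT_CHANNELS: tuple[str, ...] = tuple(
    f"{m2}T[C>T]{p1}{p2}"
    for m2 in BASES
    for p1 in "ACT"
    for p2 in BASES
)


def tri_channel(ctx: OrientedContext) -> str:
    return f"{ctx.base_at(-1)}[{ctx.substitution}]{ctx.base_at(+1)}"


def penta_ct_channel(ctx: OrientedContext) -> str | None:
    """Pentanucleotide C>T channel for TCH-context mutations, else None."""
    if ctx.substitution != "C>T" or not ctx.is_tc or ctx.base_at(+1) == "G":
        return None
    return f"{ctx.base_at(-2)}T[C>T]{ctx.base_at(+1)}{ctx.base_at(+2)}"


@dataclass
class SpectrumMatrix:
    samples: list[str]
    channels: list[str]
    counts: np.ndarray  # samples x channels, ints
    normalized: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.samples, columns=self.channels)

    def normalize(self) -> "SpectrumMatrix":
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore"):
            self.normalized = np.where(totals > 0, self.counts / totals, 0.0)
        return self


def build_spectrum(
    contexts: Iterable[OrientedContext],
    level: str = "tri",
    classes: Sequence[str] | None = None,
) -> SpectrumMatrix:
    """Per-sample mutation spectrum at the tri- or pentanucleotide level.

    ``classes`` filters pyrimidine-normalized substitution classes (e.g.
    ("C>T", "C>G")); None keeps all six.  Flagged contexts are excluded.
    At the ``penta`` level only C>T at TCH is channelled (48 channels).
    """
    if level == "tri":
        channels = list(TRI_CHANNELS)
        chan_fn = tri_channel
    elif level == "penta":
        channels = list(PENTA_CT_CHANNELS)
        chan_fn = penta_ct_channel
    else:
        raise ValueError(f"unknown spectrum level {level!r}")
    index = {c: i for i, c in enumerate(channels)}
    allowed = set(classes) if classes is not None else None

    samples: list[str] = []
    sample_index: dict[str, int] = {}
    rows: list[np.ndarray] = []
    for ctx in contexts:
        if ctx.flagged:
            continue
        if allowed is not None and ctx.substitution not in allowed:
            continue
        ch = chan_fn(ctx)
        if ch is None:
            continue
        sid = ctx.mutation.sample_id
        if sid not in sample_index:
            sample_index[sid] = len(samples)
            samples.append(sid)
            rows.append(np.zeros(len(channels), dtype=np.int64))
        rows[sample_index[sid]][index[ch]] += 1
    counts = np.vstack(rows) if rows else np.zeros((0, len(channels)), dtype=np.int64)
    return SpectrumMatrix(samples, channels, counts)


@dataclass
class MotifFractions:
    """Motif composition of oriented C>T/C>G mutations at TC dinucleotides.

    Plus-one and minus-two fractions are over all TC-context mutations;
    ``f_YTCW``/``f_RTCW`` are over the TCW subset (YTCW/NTCW, RTCW/NTCW).
    ``n_tcw_signature`` counts the APOBEC3 signature set (C>T/C>G at TCW).
    """

    n_tc: int
    n_tcw: int
    f_plus1_A: float
    f_plus1_T: float
    f_W: float
    f_minus2_Y: float
    f_minus2_R: float
    f_YTCW: float
    f_RTCW: float

    @property
    def n_tcw_signature(self) -> int:
        return self.n_tcw


def motif_fractions(contexts: Iterable[OrientedContext]) -> MotifFractions:
    """Motif fractions over oriented, unflagged C>T/C>G mutations at TC."""
    n_tc = n_tcw = 0
    plus1 = {b: 0 for b in BASES}
    minus2_y = 0
    ytcw = 0
    for ctx in contexts:
        if ctx.flagged or not ctx.is_tc or ctx.alt_oriented not in "TG":
            continue
        n_tc += 1
        p1 = ctx.base_at(+1)
        plus1[p1] += 1
        m2_is_y = ctx.base_at(-2) in "CT"
        if m2_is_y:
            minus2_y += 1
        if p1 in "AT":
            n_tcw += 1
            if m2_is_y:
                ytcw += 1
    if n_tc == 0:
        raise ValueError("no oriented C>T/C>G mutations at TC dinucleotides")
    f_ytcw = ytcw / n_tcw if n_tcw else float("nan")
    return MotifFractions(
        n_tc=n_tc,
        n_tcw=n_tcw,
        f_plus1_A=plus1["A"] / n_tc,
        f_plus1_T=plus1["T"] / n_tc,
        f_W=(plus1["A"] + plus1["T"]) / n_tc,
        f_minus2_Y=minus2_y / n_tc,
        f_minus2_R=1.0 - minus2_y / n_tc,
        f_YTCW=f_ytcw,
        f_RTCW=1.0 - f_ytcw if n_tcw else float("nan"),
    )


@dataclass
class EnrichmentResult:
    sample_id: str
    M_TCW: int
    M_C: int
    C_TCW: int
    C_C: int
    E: float
    p: float
    q: float | None = None
    undefined: bool = False


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals.sort()
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _window_motif_counts(
    genome: ReferenceSequence, windows: Mapping[str, list[tuple[int, int]]]
) -> tuple[int, int]:
    """Strand-symmetric TCW and cytosine counts over merged window intervals.

    A TCW instance is attributed to the position of its cytosine; on the
    reverse strand the motif reads WGA on the reference and is attributed to
    the G.  ``C_C`` counts C and G bases (cytosines on either strand).
    """
    c_tcw = 0
    c_c = 0
    for chrom, ivals in windows.items():
        seq = genome.contigs[chrom]
        n = len(seq)
        for s, e in _merge_intervals(list(ivals)):
            s = max(s, 0)
            e = min(e, n)
            for i in range(s, e):
                b = seq[i]
                if b == "C":
                    c_c += 1
                    if i >= 1 and i + 1 < n and seq[i - 1] == "T" and seq[i + 1] in "AT":
                        c_tcw += 1
                elif b == "G":
                    c_c += 1
                    if i + 1 < n and i >= 1 and seq[i + 1] == "A" and seq[i - 1] in "AT":
                        c_tcw += 1
    return c_tcw, c_c


def enrichment_from_counts(
    m_tcw: int, m_c: int, c_tcw: int, c_c: int, alternative: str = "greater"
) -> tuple[float, float]:
    """Enrichment score and Fisher p from the four counts.

    E = (M_TCW * C_C) / (M_C * C_TCW); the Fisher test is on the 2x2 table
    [[M_TCW, C_TCW], [M_C - M_TCW, C_C - C_TCW]].
    """
    if c_tcw == 0 or m_c == 0:
        raise ValueError("E undefined for C_TCW = 0 or M_C = 0")
    e = (m_tcw * c_c) / (m_c * c_tcw)
    table = [[m_tcw, c_tcw], [m_c - m_tcw, c_c - c_tcw]]
    _, p = stats.fisher_exact(table, alternative=alternative)
    return e, float(p)


def enrichment_score(
    contexts: Iterable[OrientedContext],
    genome: ReferenceSequence,
    window: int = 20,
    classes: Sequence[str] = ("C>T", "C>G"),
    alternative: str = "greater",
) -> list[EnrichmentResult]:
    """Per-sample TCW enrichment score with Fisher p and BH q.

    Counts oriented cytosine mutations of the given classes; context motif
    counts come from the union of +/- ``window`` nt windows around each
    mutated cytosine (deduplicated when windows overlap, strand-symmetric).
    Samples with ``C_TCW`` = 0 or ``M_C`` = 0 are flagged undefined and
    excluded from the BH correction.
    """
    allowed = set(classes)
    per_sample: dict[str, dict] = {}
    for ctx in contexts:
        if ctx.flagged or ctx.center != "C" or ctx.substitution not in allowed:
            continue
        d = per_sample.setdefault(
            ctx.mutation.sample_id, {"m_tcw": 0, "m_c": 0, "windows": {}}
        )
        d["m_c"] += 1
        if ctx.is_tcw:
            d["m_tcw"] += 1
        pos0 = ctx.mutation.pos - 1
        d["windows"].setdefault(ctx.mutation.chrom, []).append(
            (pos0 - window, pos0 + window + 1)
        )

    results: list[EnrichmentResult] = []
    for sid, d in per_sample.items():
        c_tcw, c_c = _window_motif_counts(genome, d["windows"])
        m_tcw, m_c = d["m_tcw"], d["m_c"]
        undefined = c_tcw == 0 or m_c == 0
        if undefined:
            e = float("nan")
            p = float("nan")
        else:
            e, p = enrichment_from_counts(m_tcw, m_c, c_tcw, c_c, alternative)
        results.append(
            EnrichmentResult(sid, m_tcw, m_c, c_tcw, c_c, e, p, undefined=undefined)
        )

    defined = [r for r in results if not r.undefined]
    if defined:
        qs = bh_adjust([r.p for r in defined])
        for r, q in zip(defined, qs):
            r.q = q
    return results


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q.tolist()


def cosine_similarity(a: Sequence[float], b: Sequence[float]) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors differ in length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


@dataclass
class CohortSummary:
    condition: str
    n_clones: int
    values: list[float]
    median: float
    mean: float
    sd: float
    sem: float
    p_vs_reference: float | None


def cohort_summary(
    values_by_condition: Mapping[str, Sequence[float]],
    reference: str,
) -> list[CohortSummary]:
    """Per-condition summary statistics and two-sided Welch t-tests vs reference.

    SD is the n-1 sample standard deviation; SEM = SD / sqrt(n).  Welch tests
    need >= 2 values per group; otherwise the p-value is None.
    """
    if reference not in values_by_condition:
        raise KeyError(f"reference condition {reference!r} absent")
    ref_vals = np.asarray(values_by_condition[reference], dtype=float)
    out: list[CohortSummary] = []
    for cond, vals in values_by_condition.items():
        v = np.asarray(vals, dtype=float)
        if v.size == 0:
            raise ValueError(f"condition {cond!r} has no values")
        sd = float(np.std(v, ddof=1)) if v.size > 1 else float("nan")
        p: float | None = None
        if v.size >= 2 and ref_vals.size >= 2:
            p = float(stats.ttest_ind(v, ref_vals, equal_var=False).pvalue)
        out.append(
            CohortSummary(
                condition=cond,
                n_clones=int(v.size),
                values=v.tolist(),
                median=float(np.median(v)),
                mean=float(np.mean(v)),
                sd=sd,
                sem=sd / np.sqrt(v.size) if v.size > 1 else float("nan"),
                p_vs_reference=p,
            )
        )
    return out
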