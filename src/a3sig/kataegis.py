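"""Intermutation distances and strand-coordinated clustered-mutation calls.

A kataegis event is >= ``min_members`` APOBEC3 signature mutations (C>T/C>G
at TCW) on the same reference strand with each consecutive pair within
``window`` bp (default 10 kb).  "Same reference strand" means all members
have a mutated reference C, or all a mutated reference G.  The default
chaining rule merges consecutive qualifying mutations pairwise; a strict
mode additionally bounds the whole event span by ``window``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .variant_io import MutationRecord, OrientedContext


@dataclass
class IMDTable:
    """Sorted positions and distances-to-previous, per sample and contig."""

    frame: pd.DataFrame  # sample_id, chrom, pos, imd (NaN for contig-first)


def intermutation_distances(muts: Iterable[MutationRecord]) -> IMDTable:
    """Distance of each mutation to the previous one on the same contig.

    Duplicate (sample, contig, pos) records are deduplicated with a warning;
    the first mutation on each contig has an undefined (NaN) distance.
    """
    import logging

    rows = [
        {
            "sample_id": m.sample_id,
            "chrom": m.chrom,
            "pos": m.pos,
            "ref": m.ref,
            "alt": m.alt,
        }
        for m in muts
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return IMDTable(df.assign(imd=pd.Series(dtype=float)))
    before = len(df)
    df = df.drop_duplicates(subset=["sample_id", "chrom", "pos"])
    if len(df) < before:
        logging.getLogger(__name__).warning(
            "deduplicated %d duplicate mutation records", before - len(df)
        )
    df = df.sort_values(["sample_id", "chrom", "pos"]).reset_index(drop=True)
    df["imd"] = df.groupby(["sample_id", "chrom"])["pos"].diff()
    return IMDTable(df)


@dataclass(frozen=True)
class KataegisEvent:
    sample_id: str
    contig: str
    start: int  # position of first member (1-based)
    end: int  # position of last member (1-based)
    n_members: int
    strand: str  # 'C' (reference pyrimidine) or 'G' (reference purine)
    member_indices: tuple[int, ...]


def call_kataegis(
    contexts: Sequence[OrientedContext],
    window: int = 10_000,
    min_members: int = 2,
    strict_diameter: bool = False,
) -> list[KataegisEvent]:
    """Call strand-coordinated clusters of APOBEC3 signature mutations.

    The input is filtered internally to oriented C>T/C>G at TCW.  Within each
    (sample, contig, reference strand) group, sorted mutations are chained
    while consecutive gaps are <= ``window``; chains with >= ``min_members``
    become events.  With ``strict_diameter`` a chain is additionally split so
    the span of every event is <= ``window``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    groups: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
    for i, ctx in enumerate(contexts):
        if not ctx.is_apobec_signature:
            continue
        strand = "C" if ctx.mutation.ref == "C" else "G"
        key = (ctx.mutation.sample_id, ctx.mutation.chrom, strand)
        groups.setdefault(key, []).append((ctx.mutation.pos, i))

    events: list[KataegisEvent] = []
    for (sid, contig, strand), members in groups.items():
        members.sort()
        chain: list[tuple[int, int]] = []
        for pos, idx in members:
            if chain and (
                pos - chain[-1][0] > window
                or (strict_diameter and pos - chain[0][0] > window)
            ):
                if len(chain) >= min_members:
                    events.append(_event(sid, contig, strand, chain))
                chain = []
            chain.append((pos, idx))
        if len(chain) >= min_members:
            events.append(_event(sid, contig, strand, chain))
    events.sort(key=lambda e: (e.sample_id, e.contig, e.start))
    return events


def _event(sid: str, contig: str, strand: str, chain: list[tuple[int, int]]) -> KataegisEvent:
    return KataegisEvent(
        sample_id=sid,
        contig=contig,
        start=chain[0][0],
        end=chain[-1][0],
        n_members=len(chain),
        strand=strand,
        member_indices=tuple(idx for _, idx in chain),
    )


def events_to_frame(events: Sequence[KataegisEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": e.sample_id,
                "contig": e.contig,
                "start": e.start,
                "end": e.end,
                "n_members": e.n_members,
                "strand": e.strand,
            }
            for e in events
        ]
    )
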