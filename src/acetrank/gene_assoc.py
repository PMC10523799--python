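"""Region-to-gene association: nearest TSS and basal-plus-extension domains.

The basal-plus-extension rule gives every gene a strand-aware basal domain
(default 5 kb upstream / 1 kb downstream of its TSS) extended in both
directions up to 1 Mb, truncated at the neighbouring genes' basal domains
and at chromosome bounds.  A region is associated with every gene whose
extended domain it overlaps by at least 1 bp, so one region may regulate
several genes.  Curated per-gene domain exceptions of the original web tool
are not reproduced.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._intervals import as_interval
from .io_formats import GenomicInterval, Peak, TSSAnnotation, TSSRecord


@dataclass(frozen=True)
class RegulatoryDomain:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    basal_start: int
    basal_end: int
    extended_start: int
    extended_end: int


def build_domains(
    tss: TSSAnnotation,
    upstream: int = 5000,
    downstream: int = 1000,
    max_extension: int = 1_000_000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[RegulatoryDomain]:
    """Basal-plus-extension regulatory domains for every gene.

    Extension on each side stops at the nearer of `max_extension` and the
    adjacent gene's basal boundary; basal domains themselves may overlap.
    """
    by_chrom: dict[str, list[TSSRecord]] = {}
    for r in tss:
        if chrom_sizes is not None:
            size = chrom_sizes.get(r.chrom)
            if size is not None and r.tss > size:
                raise ValueError(
                    f"TSS of {r.gene_id} at {r.tss} beyond {r.chrom} length {size}"
                )
        by_chrom.setdefault(r.chrom, []).append(r)
    domains: list[RegulatoryDomain] = []
    for chrom, recs in by_chrom.items():
        recs.sort(key=lambda r: (r.tss, r.gene_id))
        size = chrom_sizes.get(chrom) if chrom_sizes else None
        basal = []
        for r in recs:
            if r.strand == "+":
                bs, be = r.tss - upstream, r.tss + downstream
            else:
                bs, be = r.tss - downstream, r.tss + upstream
            bs = max(0, bs)
            if size is not None:
                be = min(be, size)
            basal.append((bs, be))
        for i, r in enumerate(recs):
            bs, be = basal[i]
            left_limit = basal[i - 1][1] if i > 0 else 0
            right_limit = basal[i + 1][0] if i + 1 < len(recs) else (size if size is not None else be + max_extension)
            es = max(bs - max_extension, min(left_limit, bs), 0)
            ee = min(be + max_extension, max(right_limit, be))
            if size is not None:
                ee = min(ee, size)
            domains.append(
                RegulatoryDomain(r.gene_id, chrom, r.strand, r.tss, bs, be, es, ee)
            )
    domains.sort(key=lambda d: (d.chrom, d.tss, d.gene_id))
    return domains


def signed_distance(anchor: int, tss: int, strand: str) -> int:
    """Positive when the anchor lies downstream of the TSS in gene orientation."""
    return anchor - tss if strand == "+" else tss - anchor


@dataclass(frozen=True)
class GeneAssociation:
    region: GenomicInterval
    genes: tuple[tuple[str, int], ...]  # (gene_id, signed distance), sorted by |distance|


def associate(
    regions: Sequence, domains: Sequence[RegulatoryDomain]
) -> list[GeneAssociation]:
    """Associate each region with every gene whose extended domain it
    overlaps (>= 1 bp); genes sorted by absolute distance to the region
    anchor (midpoint, or summit for peaks)."""
    by_chrom: dict[str, list[RegulatoryDomain]] = {}
    for d in domains:
        by_chrom.setdefault(d.chrom, []).append(d)
    arrays = {
        c: (
            np.array([d.extended_start for d in ds]),
            np.array([d.extended_end for d in ds]),
        )
        for c, ds in by_chrom.items()
    }
    out: list[GeneAssociation] = []
    for region in regions:
        iv = as_interval(region)
        anchor = region.anchor if isinstance(region, Peak) else iv.midpoint
        entry = arrays.get(iv.chrom)
        hits: list[tuple[int, str, int]] = []
        if entry is not None:
            starts, ends = entry
            mask = (starts < iv.end) & (ends > iv.start)
            for j in np.flatnonzero(mask):
                d = by_chrom[iv.chrom][j]
                dist = signed_distance(anchor, d.tss, d.strand)
                hits.append((abs(dist), d.gene_id, dist))
        hits.sort()
        out.append(
            GeneAssociation(iv, tuple((g, dist) for _, g, dist in hits))
        )
    return out


def nearest_tss(
    regions: Sequence, tss: TSSAnnotation
) -> list[tuple[str, int] | None]:
    """Per region, the gene with the nearest TSS to the region anchor and the
    strand-aware signed distance; ties -> lexicographically smaller gene_id.
    None for regions on chromosomes without genes."""
    if len(tss) == 0:
        raise ValueError("TSS annotation is empty")
    out: list[tuple[str, int] | None] = []
    for region in regions:
        iv = as_interval(region)
        anchor = region.anchor if isinstance(region, Peak) else iv.midpoint
        hit = tss.nearest(iv.chrom, anchor)
        if hit is None:
            out.append(None)
            continue
        rec, _ = hit
        out.append((rec.gene_id, signed_distance(anchor, rec.tss, rec.strand)))
    return out


def associations_to_frame(assocs: Sequence[GeneAssociation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [a.region.chrom for a in assocs],
            "start": [a.region.start for a in assocs],
            "end": [a.region.end for a in assocs],
            "genes": [";".join(g for g, _ in a.genes) for a in assocs],
            "distances": [";".join(str(d) for _, d in a.genes) for a in assocs],
        }
    )
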