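"""Promoter scanning, site bookkeeping and energy-threshold selection.

Every promoter window of binding-site length is threaded through a position
energy matrix; per promoter the windows are ranked by ascending energy and
only the lowest ``keep_k`` (default 200) are retained as prediction
candidates.  Predictions are compared with annotated sites under the
more-than-50%-overlap rule: a site of length Ld counts as recovered (TP) if
some predicted window overlaps it by Lo with Lo/Ld > 0.5, or - for sites
longer than the template binding site Ln - Lo/Ln > 0.5.  A predicted window
matching no site is a false positive; multiple windows on one site count a
single TP.  The classification threshold is the candidate energy maximizing
sensitivity + specificity.

Coordinates are 0-based half-open internally; file I/O accepts the 1-based
inclusive convention of curated site tables via ``one_based=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
from Bio import SeqIO

from .evaluate import ConfusionCounts
from .pem import BASE_INDEX, PEM


class Promoter(NamedTuple):
    orf_id: str
    sequence: str


class SiteAnnotation(NamedTuple):
    orf_id: str
    start: int  # 0-based half-open
    end: int

    @property
    def Ld(self) -> int:
        return self.end - self.start


class WindowScore(NamedTuple):
    orf_id: str
    offset: int
    length: int
    energy: float
    rank: int


@dataclass(frozen=True)
class ScanConfig:
    keep_k: int = 200
    overlap_fraction: float = 0.5  # strict >
    scan_reverse: bool = False

    def __post_init__(self) -> None:
        if self.keep_k < 1:
            raise ValueError("keep_k must be >= 1")
        if not 0.0 < self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must lie in (0, 1)")


# ---------------------------------------------------------------------------
# scoring


def score_windows(pem: PEM, promoter: Promoter) -> list[WindowScore]:
    """Thread every window of the promoter through the PEM.

    A window's energy is the sum of its per-position entries; windows
    containing N are kept in the count but given +inf energy so they are
    never predicted.  Ranks are 1-based after sorting by (energy, offset).
    """
    L = pem.L
    seq = promoter.sequence.upper()
    n_windows = len(seq) - L + 1
    if n_windows < 1:
        warnings.warn(f"promoter {promoter.orf_id} shorter than the binding site",
                      stacklevel=2)
        return []
    idx = np.array([BASE_INDEX.get(b, -1) for b in seq])
    energies = np.zeros(n_windows)
    has_n = np.zeros(n_windows, dtype=bool)
    for j in range(L):
        col = idx[j:j + n_windows]
        has_n |= col < 0
        energies += pem.energies[j, np.where(col < 0, 0, col)]
    energies[has_n] = np.inf
    order = sorted(range(n_windows), key=lambda k: (energies[k], k))
    ranks = np.empty(n_windows, dtype=int)
    for r, k in enumerate(order, start=1):
        ranks[k] = r
    return [WindowScore(promoter.orf_id, k, L, float(energies[k]), int(ranks[k]))
            for k in range(n_windows)]


def scan_promoters(pem: PEM, promoters: Iterable[Promoter]) -> dict[str, list[WindowScore]]:
    return {p.orf_id: score_windows(pem, p) for p in promoters}


# ---------------------------------------------------------------------------
# sites


def merge_sites(annotations: list[SiteAnnotation]) -> list[SiteAnnotation]:
    """Union overlapping or bookended intervals per ORF; sorted, disjoint output."""
    by_orf: dict[str, list[SiteAnnotation]] = {}
    for site in annotations:
        if not 0 <= site.start < site.end:
            raise ValueError(f"invalid interval {site}")
        by_orf.setdefault(site.orf_id, []).append(site)
    merged: list[SiteAnnotation] = []
    for orf_id in sorted(by_orf):
        sites = sorted(by_orf[orf_id], key=lambda s: (s.start, s.end))
        cur_start, cur_end = sites[0].start, sites[0].end
        for site in sites[1:]:
            if site.start <= cur_end:  # overlap or bookend
                cur_end = max(cur_end, site.end)
            else:
                merged.append(SiteAnnotation(orf_id, cur_start, cur_end))
                cur_start, cur_end = site.start, site.end
        merged.append(SiteAnnotation(orf_id, cur_start, cur_end))
    return merged


def window_hits_site(offset: int, length: int, site: SiteAnnotation, Ln: int,
                     overlap_fraction: float = 0.5) -> bool:
    """The more-than-50% overlap rule (relative to Ld, or Ln for long sites)."""
    lo = min(offset + length, site.end) - max(offset, site.start)
    if lo <= 0:
        return False
    if lo / site.Ld > overlap_fraction:
        return True
    return site.Ld > Ln and lo / Ln > overlap_fraction


def classify(predictions: list[WindowScore], sites: list[SiteAnnotation], Ln: int,
             config: ScanConfig | None = None) -> ConfusionCounts:
    """Count TP (sites recovered), FN (sites missed) and FP (stray windows)."""
    if Ln <= 0:
        raise ValueError("Ln must be positive")
    config = config or ScanConfig()
    frac = config.overlap_fraction
    sites_by_orf: dict[str, list[tuple[int, SiteAnnotation]]] = {}
    for i, site in enumerate(sites):
        sites_by_orf.setdefault(site.orf_id, []).append((i, site))
    hit: set[int] = set()
    fp = 0
    for w in predictions:
        matched = False
        for i, site in sites_by_orf.get(w.orf_id, ()):
            if window_hits_site(w.offset, w.length, site, Ln, frac):
                hit.add(i)
                matched = True
        if not matched:
            fp += 1
    tp = len(hit)
    return ConfusionCounts(tp=tp, fn=len(sites) - tp, fp=fp)


def kept_windows(scored: dict[str, list[WindowScore]], config: ScanConfig | None = None
                 ) -> list[WindowScore]:
    """The keep_k lowest finite-energy windows of each promoter, pooled."""
    config = config or ScanConfig()
    kept: list[WindowScore] = []
    for windows in scored.values():
        finite = [w for w in windows if np.isfinite(w.energy)]
        finite.sort(key=lambda w: (w.energy, w.offset))
        kept.extend(finite[:config.keep_k])
    return kept


def choose_threshold(scored: dict[str, list[WindowScore]], sites: list[SiteAnnotation],
                     Ln: int, config: ScanConfig | None = None
                     ) -> tuple[float, ConfusionCounts]:
    """Pick the energy cutoff maximizing sensitivity + specificity.

    Candidates are the distinct energies among the retained windows; windows
    with energy <= cutoff are the predictions.  Ties go to the lower (more
    stringent) cutoff.  The sweep is incremental; :func:`classify` on the
    selected prediction set gives identical counts.
    """
    if not sites:
        raise ValueError("threshold selection needs at least one annotated site")
    config = config or ScanConfig()
    kept = sorted(kept_windows(scored, config), key=lambda w: w.energy)
    if not kept:
        raise ValueError("no candidate windows to threshold")
    n_sites = len(sites)
    sites_by_orf: dict[str, list[tuple[int, SiteAnnotation]]] = {}
    for i, site in enumerate(sites):
        sites_by_orf.setdefault(site.orf_id, []).append((i, site))

    hits_per_window: list[list[int]] = []
    for w in kept:
        hits = [i for i, site in sites_by_orf.get(w.orf_id, ())
                if window_hits_site(w.offset, w.length, site, Ln, config.overlap_fraction)]
        hits_per_window.append(hits)

    site_hits = np.zeros(n_sites, dtype=int)
    tp = fp = 0
    best: tuple[float, float, ConfusionCounts] | None = None
    k = 0
    while k < len(kept):
        cutoff = kept[k].energy
        while k < len(kept) and kept[k].energy == cutoff:
            hits = hits_per_window[k]
            if hits:
                for i in hits:
                    if site_hits[i] == 0:
                        tp += 1
                    site_hits[i] += 1
            else:
                fp += 1
            k += 1
        se = tp / n_sites
        sp = tp / (tp + fp) if tp + fp else 0.0
        if best is None or se + sp > best[0] + 1e-12:
            best = (se + sp, cutoff, ConfusionCounts(tp=tp, fn=n_sites - tp, fp=fp))
    assert best is not None
    return best[1], best[2]


def top_rank_stats(scored: dict[str, list[WindowScore]], sites: list[SiteAnnotation],
                   Ln: int, config: ScanConfig | None = None) -> dict[str, int]:
    """Rank-1 bookkeeping: sites (and ORFs) whose best window tops its promoter."""
    config = config or ScanConfig()
    top_sites = 0
    top_orfs: set[str] = set()
    rank1 = {orf: next((w for w in ws if w.rank == 1), None) for orf, ws in scored.items()}
    for site in sites:
        w = rank1.get(site.orf_id)
        if w is not None and window_hits_site(w.offset, w.length, site, Ln,
                                              config.overlap_fraction):
            top_sites += 1
            top_orfs.add(site.orf_id)
    return {"n_top_sites": top_sites, "n_sites": len(sites),
            "n_top_orfs": len(top_orfs), "n_orfs": len({s.orf_id for s in sites})}


# ---------------------------------------------------------------------------
# I/O


def read_promoters(source) -> list[Promoter]:
    """FASTA promoters; record id = ORF id."""
    if isinstance(source, str) and "\n" not in source:
        handle = open(source)
    elif isinstance(source, str):
        import io as _io
        handle = _io.StringIO(source)
    else:
        handle = source
    return [Promoter(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]


def read_sites(source, one_based: bool = False) -> list[SiteAnnotation]:
    """BED-like TSV (orf_id, start, end); 1-based inclusive with ``one_based``."""
    if isinstance(source, str) and "\n" not in source:
        with open(source) as fh:
            text = fh.read()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    sites = []
    for line in text.strip().splitlines():
        if not line or line.startswith("#"):
            continue
        orf_id, start, end = line.split("\t")[:3]
        start, end = int(start), int(end)
        if one_based:
            start -= 1
        sites.append(SiteAnnotation(orf_id, start, end))
    return sites


def write_scan(scored: dict[str, list[WindowScore]], predictions: set[tuple[str, int]] | None = None,
               stream=None) -> str:
    """TSV report (orf_id, start, end, strand, energy, rank, predicted), 1-based inclusive."""
    lines = ["orf_id\tstart\tend\tstrand\tenergy\trank\tpredicted"]
    for orf_id in sorted(scored):
        for w in scored[orf_id]:
            pred = int(predictions is not None and (orf_id, w.offset) in predictions)
            lines.append(f"{orf_id}\t{w.offset + 1}\t{w.offset + w.length}\t+"
                         f"\t{w.energy:.6g}\t{w.rank}\t{pred}")
    text = "\n".join(lines) + "\n"
    if stream is not None:
        if isinstance(stream, str):
            with open(stream, "w") as fh:
                fh.write(text)
        else:
            stream.write(text)
    return text
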