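"""Feature annotation for methylome analysis.

Builds the annotation universe used throughout the pipeline: CpG islands
sub-typed by genomic location (promoter / intragenic / 3'UTR / intergenic),
CGI shores (2 kb flanks with island bases subtracted), coding sequences, and
promoters classified by CpG content (HCP / ICP / LCP, Weber-style criteria).

All coordinates are 0-based half-open (BED convention).  Interval sets are
plain pandas DataFrames with at least ``chrom``, ``start``, ``end`` columns;
annotated features additionally carry ``name``, ``feature_class``, ``strand``
and (where applicable) ``gene_id``.

Gene models are DataFrames with columns ``chrom``, ``start``, ``end``,
``strand``, ``gene_id``, ``utr3_len``: the TSS is the 5' end by strand and
the 3'UTR is the terminal ``utr3_len`` bases at the 3' end; the CDS is the
remainder of the gene body.
"""

from __future__ import annotations

import logging
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("medipkit")

# CGI location subtypes, shores inherit the island's subtype.
CGI_CLASSES = ("CGI_PROMOTER", "CGI_INTRAGENIC", "CGI_3UTR", "CGI_INTERGENIC")
SHORE_CLASSES = (
    "SHORE_PROMOTER",
    "SHORE_INTRAGENIC",
    "SHORE_3UTR",
    "SHORE_INTERGENIC",
)
PROMOTER_CLASSES = ("HCP", "ICP", "LCP")
ALL_CLASSES = CGI_CLASSES + SHORE_CLASSES + ("CDS",) + PROMOTER_CLASSES

BED_COLUMNS = ("chrom", "start", "end", "name", "score", "strand")


class BedFormatError(ValueError):
    """Raised for malformed BED input, with the offending line number."""


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read a BED3/BED6 file into a DataFrame sorted by (chrom, start, end).

    Track/browser/comment lines are skipped.  Malformed lines (fewer than 3
    columns, non-integer coordinates, or start >= end) raise
    :class:`BedFormatError` naming the line number.
    """
    rows = []
    n_fields = 3
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedFormatError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated "
                    f"fields, got {len(parts)}"
                )
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedFormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start < 0:
                raise BedFormatError(f"{path}: line {lineno}: start < 0")
            if start >= end:
                raise BedFormatError(
                    f"{path}: line {lineno}: start ({start}) >= end ({end})"
                )
            row = [parts[0], start, end]
            if len(parts) >= 6:
                row += [parts[3], parts[4], parts[5]]
                n_fields = max(n_fields, 6)
            elif len(parts) >= 4:
                row += [parts[3], ".", "."]
                n_fields = max(n_fields, 4)
            else:
                row += [".", ".", "."]
            rows.append(row)
    df = pd.DataFrame(rows, columns=BED_COLUMNS)
    if n_fields == 3:
        df = df[["chrom", "start", "end"]]
    elif n_fields == 4:
        df = df[["chrom", "start", "end", "name"]]
    return (
        df.sort_values(["chrom", "start", "end"], kind="mergesort")
        .reset_index(drop=True)
    )


def write_bed(features: pd.DataFrame, path) -> None:
    """Write intervals as BED (3 to 6 columns, whichever are present).

    ``feature_class`` is carried in the BED name column when no explicit
    ``name`` column exists.  Output is sorted by (chrom, start, end).
    """
    df = features.copy()
    if "name" not in df.columns and "feature_class" in df.columns:
        df["name"] = df["feature_class"]
    cols = ["chrom", "start", "end"]
    for extra in ("name", "score", "strand"):
        if extra in df.columns:
            cols.append(extra)
        else:
            break
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    with open(path, "w") as fh:
        for row in df[cols].itertuples(index=False):
            fh.write("\t".join(str(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Gene-model helpers
# ---------------------------------------------------------------------------

def gene_tss(genes: pd.DataFrame) -> np.ndarray:
    """TSS position per gene: 5' end by strand."""
    _check_strands(genes)
    return np.where(genes["strand"].to_numpy() == "+",
                    genes["start"].to_numpy(),
                    genes["end"].to_numpy() - 1)


def gene_utr3(genes: pd.DataFrame) -> pd.DataFrame:
    """3'UTR interval per gene (terminal ``utr3_len`` bases at the 3' end)."""
    _check_strands(genes)
    plus = genes["strand"].to_numpy() == "+"
    utr = genes["utr3_len"].to_numpy() if "utr3_len" in genes.columns else np.zeros(len(genes), dtype=int)
    utr = np.minimum(utr, genes["end"].to_numpy() - genes["start"].to_numpy())
    start = np.where(plus, genes["end"].to_numpy() - utr, genes["start"].to_numpy())
    end = np.where(plus, genes["end"].to_numpy(), genes["start"].to_numpy() + utr)
    return pd.DataFrame({"chrom": genes["chrom"].to_numpy(), "start": start, "end": end})


def gene_cds(genes: pd.DataFrame) -> pd.DataFrame:
    """CDS span per gene: the gene body minus the 3'UTR."""
    _check_strands(genes)
    plus = genes["strand"].to_numpy() == "+"
    utr = genes["utr3_len"].to_numpy() if "utr3_len" in genes.columns else np.zeros(len(genes), dtype=int)
    utr = np.minimum(utr, genes["end"].to_numpy() - genes["start"].to_numpy())
    start = np.where(plus, genes["start"].to_numpy(), genes["start"].to_numpy() + utr)
    end = np.where(plus, genes["end"].to_numpy() - utr, genes["end"].to_numpy())
    out = genes[["chrom", "strand", "gene_id"]].copy()
    out["start"], out["end"] = start, end
    out = out[out["start"] < out["end"]]
    out["name"] = out["gene_id"]
    out["feature_class"] = "CDS"
    return out[["chrom", "start", "end", "name", "feature_class", "strand", "gene_id"]].reset_index(drop=True)


def _check_strands(genes: pd.DataFrame) -> None:
    if "strand" not in genes.columns or not genes["strand"].isin(["+", "-"]).all():
        bad = genes.index[~genes.get("strand", pd.Series(index=genes.index, dtype=object)).isin(["+", "-"])].tolist()
        raise ValueError(f"gene(s) without a valid strand: rows {bad[:5]}")


def promoter_windows(
    genes: pd.DataFrame, upstream: int = 1000, downstream: int = 500
) -> pd.DataFrame:
    """Strand-aware promoter window [TSS-upstream, TSS+downstream) per gene."""
    tss = gene_tss(genes)
    plus = genes["strand"].to_numpy() == "+"
    start = np.where(plus, tss - upstream, tss + 1 - downstream)
    end = np.where(plus, tss + downstream, tss + 1 + upstream)
    return pd.DataFrame(
        {"chrom": genes["chrom"].to_numpy(), "start": np.maximum(start, 0),
         "end": end, "gene_id": genes["gene_id"].to_numpy(), "tss": tss}
    )


# ---------------------------------------------------------------------------
# CGI location subtyping
# ---------------------------------------------------------------------------

def classify_cgi_location(
    cgis: pd.DataFrame,
    genes: pd.DataFrame,
    promoter_upstream: int = 1000,
    promoter_downstream: int = 500,
) -> pd.DataFrame:
    """Assign each CGI exactly one location subtype.

    Precedence when a CGI overlaps several contexts:
    promoter > 3'UTR > intragenic > intergenic.  A CGI overlapping windows of
    several genes is linked to the gene with the nearest TSS (logged).

    Returns an annotated feature DataFrame with one row per input CGI.
    """
    _check_strands(genes) if len(genes) else None
    proms = promoter_windows(genes, promoter_upstream, promoter_downstream) if len(genes) else None
    utr3 = gene_utr3(genes) if len(genes) else None

    classes = np.full(len(cgis), "CGI_INTERGENIC", dtype=object)
    linked = np.full(len(cgis), "", dtype=object)

    if len(genes):
        g_by_chrom = {c: idx.to_numpy() for c, idx in genes.groupby("chrom").groups.items()}
        tss_all = gene_tss(genes)
        n_multi = 0
        cstarts = cgis["start"].to_numpy()
        cends = cgis["end"].to_numpy()
        cchroms = cgis["chrom"].to_numpy()
        for i in range(len(cgis)):
            gi = g_by_chrom.get(cchroms[i])
            if gi is None:
                continue
            s, e = cstarts[i], cends[i]
            mid = (s + e) // 2
            # candidate relations for every gene on this chromosome
            hit_prom = (proms["start"].to_numpy()[gi] < e) & (proms["end"].to_numpy()[gi] > s)
            hit_utr = (utr3["start"].to_numpy()[gi] < e) & (utr3["end"].to_numpy()[gi] > s)
            hit_body = (genes["start"].to_numpy()[gi] < e) & (genes["end"].to_numpy()[gi] > s)
            for mask, label in (
                (hit_prom, "CGI_PROMOTER"),
                (hit_utr, "CGI_3UTR"),
                (hit_body, "CGI_INTRAGENIC"),
            ):
                if mask.any():
                    cand = gi[mask]
                    if len(cand) > 1:
                        n_multi += 1
                        cand = cand[np.argsort(np.abs(tss_all[cand] - mid), kind="stable")]
                    classes[i] = label
                    linked[i] = genes["gene_id"].to_numpy()[cand[0]]
                    break
        if n_multi:
            logger.info("classify_cgi_location: %d CGIs overlapped multiple "
                        "genes; assigned to nearest TSS", n_multi)

    out = cgis[["chrom", "start", "end"]].copy().reset_index(drop=True)
    out["name"] = [f"CGI_{i:05d}" for i in range(len(out))]
    out["feature_class"] = classes
    out["strand"] = "."
    out["gene_id"] = linked
    return out


# ---------------------------------------------------------------------------
# CGI shores
# ---------------------------------------------------------------------------

def make_shores(
    cgis: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    shore_size: int = 2000,
) -> pd.DataFrame:
    """Build the two ``shore_size``-bp flanks of every CGI.

    Flanks are clipped at chromosome ends and any bases falling inside
    another CGI are subtracted, so shores never overlap island bases.  When
    the input carries a ``feature_class`` (CGI subtypes), shores inherit the
    parent subtype (CGI_X -> SHORE_X).
    """
    if len(cgis) == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "name", "feature_class", "strand", "gene_id"]
        )
    has_class = "feature_class" in cgis.columns
    pieces = []
    for chrom, sub in cgis.groupby("chrom"):
        sub = sub.sort_values("start")
        L = int(chrom_lengths[chrom])
        # merged island intervals for subtraction
        merged_s, merged_e = _merge(sub["start"].to_numpy(), sub["end"].to_numpy())
        for row in sub.itertuples(index=False):
            subclass = (
                row.feature_class.replace("CGI_", "SHORE_") if has_class else "SHORE"
            )
            gene = getattr(row, "gene_id", "")
            for fs, fe in (
                (max(0, row.start - shore_size), row.start),
                (row.end, min(L, row.end + shore_size)),
            ):
                for ps, pe in _subtract(fs, fe, merged_s, merged_e):
                    pieces.append((chrom, ps, pe, subclass, gene))
    out = pd.DataFrame(pieces, columns=["chrom", "start", "end", "feature_class", "gene_id"])
    out = out[out["start"] < out["end"]].reset_index(drop=True)
    out = out.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    out["name"] = [f"SHORE_{i:05d}" for i in range(len(out))]
    out["strand"] = "."
    return out[["chrom", "start", "end", "name", "feature_class", "strand", "gene_id"]]


def _merge(starts: np.ndarray, ends: np.ndarray):
    order = np.argsort(starts, kind="stable")
    ms, me = [], []
    for s, e in zip(starts[order], ends[order]):
        if me and s <= me[-1]:
            me[-1] = max(me[-1], e)
        else:
            ms.append(s)
            me.append(e)
    return np.asarray(ms), np.asarray(me)


def _subtract(s: int, e: int, block_s: np.ndarray, block_e: np.ndarray):
    """Yield the sub-intervals of [s, e) not covered by the merged blocks."""
    if s >= e:
        return
    lo = np.searchsorted(block_e, s, side="right")
    cur = s
    for bs, be in zip(block_s[lo:], block_e[lo:]):
        if bs >= e:
            break
        if bs > cur:
            yield (cur, min(bs, e))
        cur = max(cur, be)
        if cur >= e:
            return
    if cur < e:
        yield (cur, e)


# ---------------------------------------------------------------------------
# Promoter CpG-content classes (HCP / ICP / LCP)
# ---------------------------------------------------------------------------

def cpg_oe_ratio(n_cpg: float, gc_fraction: float, length: int) -> float:
    """CpG observed/expected ratio.

    ratio = (#CpG x L) / (#C x #G) with #C = #G = gc_fraction * L / 2, i.e.
    4 * #CpG / (gc^2 * L).  Zero when the window has no C or G.
    """
    if gc_fraction <= 0 or length <= 0:
        return 0.0
    return 4.0 * n_cpg / (gc_fraction * gc_fraction * length)


def classify_promoters(
    genes: pd.DataFrame,
    cpg_positions: Mapping[str, np.ndarray],
    gc_fraction: float | Callable[[str, int, int], float],
    chrom_lengths: Mapping[str, int] | None = None,
    upstream: int = 700,
    downstream: int = 200,
    subwindow: int = 500,
    substep: int = 50,
    gc_min: float = 0.55,
    hcp_ratio: float = 0.75,
    lcp_ratio: float = 0.48,
) -> pd.DataFrame:
    """Classify each gene promoter as HCP, ICP or LCP.

    The promoter window is [TSS-upstream, TSS+downstream) (strand-aware).
    Sliding ``subwindow``-bp sub-windows (step ``substep``) are scanned:
    HCP if any sub-window has GC >= ``gc_min`` and CpG o/e >= ``hcp_ratio``;
    LCP if no sub-window reaches ``lcp_ratio``; ICP otherwise.

    ``gc_fraction`` is either a constant or a callable ``(chrom, start, end)
    -> GC fraction`` (for synthetic genomes GC derives from a configured
    track rather than literal sequence).  Windows extending past chromosome
    ends are clipped; windows shorter than ``subwindow`` are classified on
    the full window (logged).
    """
    gc_fn = gc_fraction if callable(gc_fraction) else (lambda c, s, e: float(gc_fraction))
    wins = promoter_windows(genes, upstream, downstream)
    n_short = 0
    classes = []
    for row in wins.itertuples(index=False):
        s, e = int(row.start), int(row.end)
        if chrom_lengths is not None:
            e = min(e, int(chrom_lengths[row.chrom]))
        s = max(s, 0)
        pos = np.asarray(cpg_positions.get(row.chrom, ()), dtype=np.int64)
        if e - s <= subwindow:
            n_short += 1
            starts = [s]
            win_end = e
            wlen = e - s
        else:
            starts = list(range(s, e - subwindow + 1, substep))
            if starts[-1] + subwindow < e:
                starts.append(e - subwindow)
            win_end = None
            wlen = subwindow
        max_ratio = 0.0
        is_hcp = False
        for ws in starts:
            we = win_end if win_end is not None else ws + wlen
            n_cpg = int(np.searchsorted(pos, we) - np.searchsorted(pos, ws))
            gc = gc_fn(row.chrom, ws, we)
            ratio = cpg_oe_ratio(n_cpg, gc, we - ws)
            max_ratio = max(max_ratio, ratio)
            if gc >= gc_min and ratio >= hcp_ratio:
                is_hcp = True
        if is_hcp:
            classes.append("HCP")
        elif max_ratio < lcp_ratio:
            classes.append("LCP")
        else:
            classes.append("ICP")
    if n_short:
        logger.info("classify_promoters: %d promoter windows shorter than "
                    "%d bp classified on the full window", n_short, subwindow)
    out = pd.DataFrame(
        {
            "chrom": wins["chrom"],
            "start": wins["start"],
            "end": wins["end"],
            "name": [f"PROM_{g}" for g in wins["gene_id"]],
            "feature_class": classes,
            "strand": genes["strand"].to_numpy(),
            "gene_id": wins["gene_id"],
        }
    )
    return out


# ---------------------------------------------------------------------------
# Full annotation universe
# ---------------------------------------------------------------------------

def annotate_features(
    cgis: pd.DataFrame,
    genes: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    cpg_positions: Mapping[str, Sequence[int]],
    gc_fraction: float | Callable[[str, int, int], float] = 0.41,
    shore_size: int = 2000,
    promoter_upstream: int = 1000,
    promoter_downstream: int = 500,
    **promoter_kwargs,
) -> pd.DataFrame:
    """Build the complete feature universe: subtyped CGIs, shores, CDSs and
    HCP/ICP/LCP promoters, as one annotated DataFrame with unique ids."""
    cgi_ann = classify_cgi_location(cgis, genes, promoter_upstream, promoter_downstream)
    shores = make_shores(cgi_ann, chrom_lengths, shore_size)
    parts = [cgi_ann, shores]
    if len(genes):
        parts.append(gene_cds(genes))
        parts.append(
            classify_promoters(genes, {c: np.asarray(p) for c, p in cpg_positions.items()},
                               gc_fraction, chrom_lengths, **promoter_kwargs)
        )
    out = pd.concat(parts, ignore_index=True)
    out["name"] = [f"F{i:05d}_{c}" for i, c in enumerate(out["feature_class"])]
    return out
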