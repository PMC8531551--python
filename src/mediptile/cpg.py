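"""CpG-density promoter classification and DMR composition summaries.

Promoters are classified into high/intermediate/low CpG classes (HCP/ICP/
LCP) from sequence alone, by scanning windows for GC fraction and the CpG
observed/expected ratio:

    o/e = (#CpG dinucleotides × N) / (#C × #G)

with N the number of unambiguous bases in the window. A promoter is HCP if
any window has GC > 0.55 and o/e > 0.75; LCP if no window reaches
o/e > 0.48; ICP otherwise. Both the sequence and its reverse complement are
scanned — CpG is palindromic but GC windows can differ at the edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

HCP, ICP, LCP = "HCP", "ICP", "LCP"
CLASS_ORDER = (LCP, ICP, HCP)

_RC = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def cpg_observed_expected(seq: str) -> float:
    """CpG observed/expected ratio of a sequence window.

    Non-ACGT characters are excluded from all counts; returns 0 when the
    window has no C or no G.
    """
    s = seq.upper()
    n = sum(s.count(b) for b in "ACGT")
    if n == 0:
        return 0.0
    c = s.count("C")
    g = s.count("G")
    if c == 0 or g == 0:
        return 0.0
    cpg = s.count("CG")
    return cpg * n / (c * g)


def gc_fraction(seq: str) -> float:
    s = seq.upper()
    n = sum(s.count(b) for b in "ACGT")
    if n == 0:
        return 0.0
    return (s.count("C") + s.count("G")) / n


@dataclass(frozen=True)
class CpGClassification:
    promoter_id: str
    cls: str  # HCP | ICP | LCP
    best_window: tuple[int, int, float, float]  # start, end, gc, o/e (on best strand)


def _window_stats(seq: str, window_bp: int, step: int, max_n_frac: float):
    """GC and o/e for every window start (vectorized); None row if skipped."""
    s = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    L = len(s)
    is_c = (s == ord("C")).astype(np.int32)
    is_g = (s == ord("G")).astype(np.int32)
    is_acgt = np.isin(s, np.frombuffer(b"ACGT", dtype=np.uint8)).astype(np.int32)
    is_cg = np.zeros(L, dtype=np.int32)
    if L > 1:
        is_cg[:-1] = (s[:-1] == ord("C")) & (s[1:] == ord("G"))

    def cums(x):
        out = np.zeros(L + 1, dtype=np.int64)
        np.cumsum(x, out=out[1:])
        return out

    cc, cg_, cacgt, ccpg = cums(is_c), cums(is_g), cums(is_acgt), cums(is_cg)

    if L <= window_bp:
        starts = np.array([0])
        w = L
    else:
        starts = np.arange(0, L - window_bp + 1, step)
        w = window_bp
    ends = starts + w
    n_eff = cacgt[ends] - cacgt[starts]
    c = cc[ends] - cc[starts]
    g = cg_[ends] - cg_[starts]
    # CpG pairs fully inside the window
    cpg = ccpg[np.maximum(ends - 1, starts)] - ccpg[starts]
    ok = (w - n_eff) <= max_n_frac * w
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(n_eff > 0, (c + g) / np.maximum(n_eff, 1), 0.0)
        oe = np.where((c > 0) & (g > 0), cpg * n_eff / np.maximum(c * g, 1), 0.0)
    return starts, ends, gc, oe, ok


def classify_promoter(
    promoter_id: str,
    seq: str,
    window_bp: int = 500,
    step: int = 5,
    gc_min: float = 0.55,
    oe_high: float = 0.75,
    oe_low: float = 0.48,
    max_n_frac: float = 0.10,
) -> CpGClassification:
    """Assign the HCP/ICP/LCP class of one promoter sequence.

    Shorter sequences than window_bp are scanned as a single whole-sequence
    window. Windows with more than max_n_frac ambiguous bases are skipped.
    """
    if len(seq) == 0:
        raise ValueError(f"empty sequence for promoter {promoter_id}")
    any_hcp = False
    any_mid = False
    best = (0, min(len(seq), window_bp), 0.0, 0.0)
    best_key = (-1, -1.0, -1.0)
    for strand_seq in (seq, reverse_complement(seq)):
        starts, ends, gc, oe, ok = _window_stats(strand_seq, window_bp, step, max_n_frac)
        if not ok.any():
            continue
        hcp_win = ok & (gc > gc_min) & (oe > oe_high)
        any_hcp |= bool(hcp_win.any())
        any_mid |= bool((ok & (oe > oe_low)).any())
        key = np.where(hcp_win, 1, 0) * 10 + oe  # prefer HCP-qualifying windows
        i = int(np.argmax(np.where(ok, key, -np.inf)))
        cand = (int(hcp_win[i]), float(oe[i]), float(gc[i]))
        if cand > best_key:
            best_key = cand
            best = (int(starts[i]), int(ends[i]), float(gc[i]), float(oe[i]))
    cls = HCP if any_hcp else (ICP if any_mid else LCP)
    return CpGClassification(promoter_id=promoter_id, cls=cls, best_window=best)


def classify_fasta(records, **kwargs) -> pd.DataFrame:
    """Classify an iterable of (id, sequence) pairs or Bio.SeqRecords.

    Returns a DataFrame with PROMOTER_ID, CLASS and best-window stats.
    """
    rows = []
    for rec in records:
        if hasattr(rec, "seq"):
            pid, seq = rec.id, str(rec.seq)
        else:
            pid, seq = rec
        c = classify_promoter(pid, seq, **kwargs)
        rows.append((c.promoter_id, c.cls, *c.best_window))
    return pd.DataFrame(
        rows,
        columns=["PROMOTER_ID", "CLASS", "WIN_START", "WIN_END", "GC", "CPG_OE"],
    )


@dataclass
class CompositionReport:
    """DMR composition by direction, CpG class and chromosome."""

    total: int
    by_direction: pd.DataFrame
    by_class: pd.DataFrame
    by_chromosome: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for name, df in (
            ("direction", self.by_direction),
            ("cpg_class", self.by_class),
            ("chromosome", self.by_chromosome),
        ):
            d = df.copy()
            d.insert(0, "PARTITION", name)
            parts.append(d)
        return pd.concat(parts, ignore_index=True)


def _tabulate(series: pd.Series, order=None) -> pd.DataFrame:
    counts = series.value_counts()
    if order is not None:
        counts = counts.reindex([o for o in order if o in counts.index])
    total = int(counts.sum())
    pct = (
        (100.0 * counts / total).round(2)
        if total > 0
        else pd.Series(np.nan, index=counts.index)
    )
    return pd.DataFrame(
        {"CATEGORY": counts.index, "COUNT": counts.to_numpy(), "PERCENT": pct.to_numpy()}
    )


def summarize_dmrs(
    dmrs: pd.DataFrame, classes: pd.DataFrame | dict | None = None
) -> CompositionReport:
    """Counts and percentages of DMRs by direction, CpG class and chromosome.

    ``dmrs`` is a DMR table (needs DIRECTION, GENE_ID, CHR); ``classes``
    maps promoter/gene id to HCP/ICP/LCP (DataFrame with PROMOTER_ID+CLASS,
    or a dict). Percentages are 100×count/total rounded to 2 decimals; an
    empty call set yields zero counts and NA percentages. A DMR whose
    promoter is unclassified is an error.
    """
    if classes is None:
        class_map = {}
    elif isinstance(classes, dict):
        class_map = classes
    else:
        class_map = dict(zip(classes["PROMOTER_ID"], classes["CLASS"]))

    total = len(dmrs)
    if total == 0:
        empty = pd.DataFrame({"CATEGORY": [], "COUNT": [], "PERCENT": []})
        return CompositionReport(0, empty, empty.copy(), empty.copy())

    by_dir = _tabulate(dmrs["DIRECTION"], order=("hyper", "hypo"))
    if classes is not None:
        missing = [g for g in dmrs["GENE_ID"] if g not in class_map]
        if missing:
            raise ValueError(f"unclassified promoter(s): {missing[:5]}")
        cls = dmrs["GENE_ID"].map(class_map)
        by_cls = _tabulate(cls, order=(HCP, ICP, LCP))
    else:
        by_cls = pd.DataFrame({"CATEGORY": [], "COUNT": [], "PERCENT": []})
    by_chrom = _tabulate(dmrs["CHR"])
    return CompositionReport(total, by_dir, by_cls, by_chrom)
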