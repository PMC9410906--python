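"""Promoter extraction, sigma70 core elements, inverted repeats, motifs.

The core-promoter scanner replaces a closed-source predictor with a
transparent consensus-matrix scan: position weight matrices derived from the
sigma70 consensus hexamers TTGACA (-35) and TATAAT (-10), a spacer of 15-19 nt
penalised by 0.5 bits per base of deviation from the 17 nt optimum, and an
empirically calibratable significance threshold. Inverted repeats (IRs) are
enumerated exhaustively with a mismatch budget and reported only when maximal
(no one-base arm extension stays within the budget and bounds). Motif
discovery is a strand-aware Gibbs sampler (OOPS/ZOOPS) over promoter sets,
replacing EM-based discovery; motif comparison uses mean per-column Pearson
correlation of frequency vectors over all offsets and orientations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .genomic_context import Operon
from .records import GenomeRecord, revcomp

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

SIGMA70_MINUS35 = "TTGACA"
SIGMA70_MINUS10 = "TATAAT"
SPACER_OPTIMUM = 17
SPACER_PENALTY_BITS = 0.5  # per base of deviation from the optimum
CONSENSUS_MATCH_PROB = 0.8  # documented hexamer matrix: P(consensus base)

# default significance threshold (bits); pipelines calibrate this on
# background nulls, see calibrate_core_threshold
DEFAULT_CORE_THRESHOLD = 12.0


@dataclass
class PromoterRegion:
    """Upstream window of an operon leader, coding-strand oriented.

    ``sequence[-1]`` is position -1, the base adjacent to the start codon.
    """

    operon_id: str
    contig_id: str
    start: int  # genomic, 0-based half-open
    end: int
    strand: str
    sequence: str
    clipped: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ElementCall:
    position: int  # offset in the promoter sequence, 0-based
    hexamer: str
    score: float


@dataclass
class CorePromoterCall:
    minus35: ElementCall
    minus10: ElementCall
    spacer: int
    total_score: float
    significant: bool

    @property
    def span(self) -> tuple[int, int]:
        """Core promoter span: -35 start through -10 end (half-open)."""
        return self.minus35.position, self.minus10.position + 6


@dataclass
class InvertedRepeat:
    left: tuple[int, int]  # arm intervals, 0-based half-open, left strictly 5'
    right: tuple[int, int]
    arm_length: int
    spacer: int
    mismatches: int
    classification: str = "unclassified"  # IR1 | IR2 | unclassified

    @property
    def span(self) -> tuple[int, int]:
        return self.left[0], self.right[1]


@dataclass
class Motif:
    counts: np.ndarray  # (width, 4)
    background: np.ndarray  # (4,)
    sites: list[tuple[str, int, str]] = field(default_factory=list)
    pseudocount: float = 0.25

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def n_sites(self) -> int:
        return int(round(self.counts[0].sum())) if self.width else 0

    @property
    def frequencies(self) -> np.ndarray:
        """Pseudocount-free column frequencies (for IC and motif comparison)."""
        totals = self.counts.sum(axis=1, keepdims=True)
        return np.divide(
            self.counts, totals, out=np.zeros_like(self.counts), where=totals > 0
        )

    @property
    def log_odds(self) -> np.ndarray:
        """Pseudocount-regularised log2 odds versus background."""
        totals = self.counts.sum(axis=1, keepdims=True)
        p = (self.counts + self.pseudocount) / (totals + 4 * self.pseudocount)
        return np.log2(p / self.background)

    @property
    def information_content(self) -> float:
        """Total bits: sum over columns of 2 + sum_b p log2 p (uniform bg)."""
        p = self.frequencies
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        return float((2.0 + plogp.sum(axis=1)).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[j] for j in self.counts.argmax(axis=1))


def encode_dna(seq: str) -> np.ndarray:
    return np.array([BASE_INDEX.get(b, 0) for b in seq.upper()], dtype=np.int64)


def extract_promoter(
    genome: GenomeRecord, operon: Operon, length: int = 400
) -> PromoterRegion:
    """The up-to-``length`` bases upstream of the operon leader, coding-oriented.

    Clipped at contig edges (shorter region, flagged); a leader flush with
    the contig edge yields an empty, flagged region.
    """
    leader = operon.leader
    if operon.strand == "+":
        s, e = max(0, leader.start - length), leader.start
        seq = genome.sequence[s:e]
    else:
        s, e = leader.end, min(len(genome.sequence), leader.end + length)
        seq = revcomp(genome.sequence[s:e])
    return PromoterRegion(
        operon_id=operon.operon_id,
        contig_id=genome.contig_id,
        start=s,
        end=e,
        strand=operon.strand,
        sequence=seq,
        clipped=(e - s) < length,
    )


def consensus_pwm(hexamer: str, match_prob: float = CONSENSUS_MATCH_PROB) -> np.ndarray:
    """log2-odds matrix vs uniform background from a consensus string."""
    w = len(hexamer)
    p = np.full((w, 4), (1 - match_prob) / 3)
    for j, b in enumerate(hexamer):
        p[j, BASE_INDEX[b]] = match_prob
    return np.log2(p / 0.25)


_PWM35 = consensus_pwm(SIGMA70_MINUS35)
_PWM10 = consensus_pwm(SIGMA70_MINUS10)


def _pwm_scores(pwm: np.ndarray, idx: np.ndarray) -> np.ndarray:
    w = pwm.shape[0]
    if len(idx) < w:
        return np.empty(0)
    windows = sliding_window_view(idx, w)
    return pwm[np.arange(w), windows].sum(axis=1)


def scan_core_promoter(
    region: PromoterRegion | str,
    search_window: int = 150,
    spacer_range: tuple[int, int] = (15, 19),
    threshold: float = DEFAULT_CORE_THRESHOLD,
) -> CorePromoterCall | None:
    """Best-scoring -35/-10 pair within the 3'-most ``search_window`` bases.

    total = pwm(-35) + pwm(-10) - 0.5*|spacer - 17|; ties go to the 3'-most
    -10, then the longest spacer. Returns None when no placement fits.
    """
    seq = region.sequence if isinstance(region, PromoterRegion) else region
    if not seq:
        return None
    idx = encode_dna(seq)
    lo = max(0, len(seq) - search_window)
    s35 = _pwm_scores(_PWM35, idx)
    s10 = _pwm_scores(_PWM10, idx)
    best = None  # key: (total, m10_pos, spacer)
    for m10_pos in range(len(seq) - 6, lo - 1, -1):
        for spacer in range(spacer_range[1], spacer_range[0] - 1, -1):
            m35_pos = m10_pos - spacer - 6
            if m35_pos < lo:
                continue
            total = (
                s35[m35_pos]
                + s10[m10_pos]
                - SPACER_PENALTY_BITS * abs(spacer - SPACER_OPTIMUM)
            )
            key = (total, m10_pos, spacer)
            if best is None or key > best:
                best = key
    if best is None:
        return None
    total, m10_pos, spacer = best
    m35_pos = m10_pos - spacer - 6
    return CorePromoterCall(
        minus35=ElementCall(m35_pos, seq[m35_pos : m35_pos + 6], float(s35[m35_pos])),
        minus10=ElementCall(m10_pos, seq[m10_pos : m10_pos + 6], float(s10[m10_pos])),
        spacer=spacer,
        total_score=float(total),
        significant=bool(total >= threshold),
    )


def calibrate_core_threshold(
    background_seqs: list[str],
    quantile: float = 0.99,
    search_window: int = 150,
    spacer_range: tuple[int, int] = (15, 19),
) -> float:
    """Significance threshold: quantile of best scores on background sequences."""
    scores = []
    for seq in background_seqs:
        call = scan_core_promoter(
            PromoterRegion("bg", "bg", 0, len(seq), "+", seq),
            search_window=search_window,
            spacer_range=spacer_range,
            threshold=np.inf,
        )
        if call is not None:
            scores.append(call.total_score)
    if not scores:
        raise ValueError("no scorable background sequences")
    return float(np.quantile(np.array(scores), quantile))


def find_inverted_repeats(
    seq: str,
    arm_range: tuple[int, int] = (4, 10),
    spacer_range: tuple[int, int] = (0, 12),
    max_mismatch: int = 1,
) -> list[InvertedRepeat]:
    """All maximal inverted repeats within the mismatch budget.

    An IR (left start l, arm a, spacer s) counts mismatches between the left
    arm and the reverse complement of the right arm. It is maximal when
    neither the outward extension (l-1, a+1, s) nor the inward extension
    (l, a+1, s-2) is itself a valid IR (within sequence bounds, arm/spacer
    bounds, and the mismatch budget); nested sub-IRs are thereby suppressed.
    Sorted by (descending arm length, ascending mismatches, position).
    """
    amin, amax = arm_range
    smin, smax = spacer_range
    if amin < 2:
        raise ValueError("minimum arm length must be >= 2")
    L = len(seq)
    idx = encode_dna(seq)
    comp = 3 - idx
    mism: dict[tuple[int, int], np.ndarray] = {}
    for arm in range(amin, amax + 1):
        if 2 * arm > L:
            break
        left = sliding_window_view(idx, arm)  # left[l] = seq[l:l+arm]
        right_rc = sliding_window_view(comp, arm)[:, ::-1]  # revcomp of seq[r:r+arm]
        for spacer in range(smin, smax + 1):
            n = L - (2 * arm + spacer) + 1
            if n <= 0:
                continue
            mism[(arm, spacer)] = (left[:n] != right_rc[arm + spacer : arm + spacer + n]).sum(
                axis=1
            )

    def valid(l: int, arm: int, spacer: int) -> bool:
        if not (amin <= arm <= amax and smin <= spacer <= smax and l >= 0):
            return False
        arr = mism.get((arm, spacer))
        return arr is not None and l < len(arr) and arr[l] <= max_mismatch

    out: list[InvertedRepeat] = []
    for (arm, spacer), arr in mism.items():
        for l in np.flatnonzero(arr <= max_mismatch):
            l = int(l)
            if valid(l - 1, arm + 1, spacer) or valid(l, arm + 1, spacer - 2):
                continue
            rs = l + arm + spacer
            out.append(
                InvertedRepeat(
                    left=(l, l + arm),
                    right=(rs, rs + arm),
                    arm_length=arm,
                    spacer=spacer,
                    mismatches=int(arr[l]),
                )
            )
    out.sort(key=lambda ir: (-ir.arm_length, ir.mismatches, ir.left[0], ir.spacer))
    return out


def classify_ir(ir: InvertedRepeat, core: CorePromoterCall | None) -> str:
    """IR1 if the IR span overlaps the core-promoter span by >= 1 base, IR2 if
    disjoint, unclassified with no core call."""
    if core is None:
        return "unclassified"
    if ir.left[0] < 0 or core.minus35.position < 0:
        raise ValueError("coordinate frame mismatch")
    ir_s, ir_e = ir.span
    core_s, core_e = core.span
    return "IR1" if min(ir_e, core_e) - max(ir_s, core_s) >= 1 else "IR2"


def classify_promoter_irs(
    irs: list[InvertedRepeat], core: CorePromoterCall | None
) -> list[InvertedRepeat]:
    return [replace(ir, classification=classify_ir(ir, core)) for ir in irs]


# ---------------------------------------------------------------------------
# Gibbs motif discovery


def _as_named_seqs(promoters) -> list[tuple[str, str]]:
    named = []
    for i, p in enumerate(promoters):
        if isinstance(p, PromoterRegion):
            named.append((p.operon_id, p.sequence))
        elif isinstance(p, tuple):
            named.append(p)
        else:
            named.append((f"seq{i}", p))
    return named


def _site_window(idx: np.ndarray, comp: np.ndarray, off: int, strand: str, w: int) -> np.ndarray:
    return idx[off : off + w] if strand == "+" else comp[off : off + w][::-1]


def discover_motif(
    promoters,
    width: int = 18,
    mode: str = "zoops",
    n_restarts: int = 5,
    iterations: int = 200,
    seed: int = 0,
    background: np.ndarray | None = None,
) -> Motif:
    """Gibbs-sampling motif discovery over both strands.

    One site per sequence (OOPS) or at most one (ZOOPS): each sweep removes a
    sequence's site, rebuilds the motif from the rest (pseudocount 0.25 per
    base), and resamples the site from the posterior over every window on
    both strands; in ZOOPS a no-site option competes with weight equal to the
    window count (a flat-odds prior). Every 10 sweeps a phase-shift move
    slides all sites together by up to 3 columns if that raises the motif
    log-likelihood, curing the register drift Gibbs site samplers are prone
    to. Best of ``n_restarts`` by information content x site count.
    Deterministic for a fixed seed.
    """
    if mode not in ("oops", "zoops"):
        raise ValueError("mode must be 'oops' or 'zoops'")
    named = _as_named_seqs(promoters)
    if len(named) < 2:
        raise ValueError("need at least 2 promoter sequences")
    if any(len(s) < width for _, s in named):
        raise ValueError("motif width exceeds the shortest promoter")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    n = len(named)
    enc = [encode_dna(s) for _, s in named]
    cmp_ = [3 - e for e in enc]
    fwd = [sliding_window_view(e, width) for e in enc]
    rc = [sliding_window_view(c, width)[:, ::-1] for c in cmp_]
    log_bg_win = [np.log2(bg[w]).sum(axis=1) for w in fwd]  # per-window bg loglik
    log_bg_rc = [np.log2(bg[w]).sum(axis=1) for w in rc]
    master = np.random.default_rng(seed)
    restart_seeds = master.integers(2**31, size=n_restarts)

    best: tuple[float, Motif] | None = None
    cols = np.arange(width)
    n_windows = [len(f) for f in fwd]

    def _counts_for(sites: list[tuple[int, str] | None]) -> np.ndarray:
        c = np.zeros((width, 4))
        for i, s in enumerate(sites):
            if s is not None:
                c[cols, _site_window(enc[i], cmp_[i], s[0], s[1], width)] += 1
        return c

    def _loglik(c: np.ndarray) -> float:
        total = c.sum(axis=1, keepdims=True)
        if total.max() == 0:
            return -np.inf
        p = (c + 0.25) / (total + 1.0)
        return float((c * np.log2(p)).sum())

    def _shifted(sites, delta):
        """All sites slid by delta motif columns; None if any falls off an edge."""
        out = []
        for i, s in enumerate(sites):
            if s is None:
                out.append(None)
                continue
            off, strand = s
            # '+' sites move with the sequence; '-' sites mirror the shift
            new = off + delta if strand == "+" else off - delta
            if not 0 <= new < n_windows[i]:
                return None
            out.append((new, strand))
        return out

    for rseed in restart_seeds:
        rng = np.random.default_rng(int(rseed))
        sites: list[tuple[int, str] | None] = []
        counts = np.zeros((width, 4))
        for i in range(n):
            off = int(rng.integers(len(fwd[i])))
            strand = "+" if rng.random() < 0.5 else "-"
            sites.append((off, strand))
            win = _site_window(enc[i], cmp_[i], off, strand, width)
            counts[cols, win] += 1
        for sweep in range(iterations):
            if sweep and sweep % 10 == 0:
                cur_ll = _loglik(counts)
                best_shift = None
                for delta in (-3, -2, -1, 1, 2, 3):
                    cand = _shifted(sites, delta)
                    if cand is None:
                        continue
                    ll = _loglik(_counts_for(cand))
                    if ll > cur_ll and (best_shift is None or ll > best_shift[0]):
                        best_shift = (ll, cand)
                if best_shift is not None:
                    sites = best_shift[1]
                    counts = _counts_for(sites)
            for i in range(n):
                if sites[i] is not None:
                    off, strand = sites[i]
                    counts[cols, _site_window(enc[i], cmp_[i], off, strand, width)] -= 1
                    sites[i] = None
                total = counts.sum(axis=1, keepdims=True)
                logp = np.log2((counts + 0.25) / (total + 1.0))
                sf = logp[cols, fwd[i]].sum(axis=1) - log_bg_win[i]
                sr = logp[cols, rc[i]].sum(axis=1) - log_bg_rc[i]
                logw = np.concatenate([sf, sr])
                n_win = len(sf)
                if mode == "zoops":
                    logw = np.concatenate([logw, [np.log2(float(2 * n_win))]])
                w = np.exp2(logw - logw.max())
                w /= w.sum()
                pick = int(rng.choice(len(w), p=w))
                if mode == "zoops" and pick == 2 * n_win:
                    continue  # no site for this sequence this sweep
                off, strand = (pick, "+") if pick < n_win else (pick - n_win, "-")
                sites[i] = (off, strand)
                counts[cols, _site_window(enc[i], cmp_[i], off, strand, width)] += 1
        site_list = [
            (named[i][0], s[0], s[1]) for i, s in enumerate(sites) if s is not None
        ]
        motif = Motif(counts.copy(), bg, site_list)
        objective = motif.information_content * len(site_list)
        if best is None or objective > best[0]:
            best = (objective, motif)
    return best[1]


def discover_motif_sweep(
    promoters,
    widths=range(10, 25, 2),
    **kwargs,
) -> Motif:
    """Run discovery over a width sweep; keep the max IC-per-column motif."""
    best = None
    for w in widths:
        try:
            m = discover_motif(promoters, width=w, **kwargs)
        except ValueError:
            continue
        per_col = m.information_content / m.width
        if best is None or per_col > best[0]:
            best = (per_col, m)
    if best is None:
        raise ValueError("no width in the sweep fits the promoter set")
    return best[1]


def scan_motif(
    motif: Motif, region: PromoterRegion | str, score_threshold: float
) -> list[tuple[int, str, float]]:
    """All windows on both strands scoring >= threshold, sorted by position."""
    seq = region.sequence if isinstance(region, PromoterRegion) else region
    w = motif.width
    if len(seq) < w:
        return []
    idx = encode_dna(seq)
    comp = 3 - idx
    lo = motif.log_odds
    cols = np.arange(w)
    sf = lo[cols, sliding_window_view(idx, w)].sum(axis=1)
    sr = lo[cols, sliding_window_view(comp, w)[:, ::-1]].sum(axis=1)
    hits = [(int(i), "+", float(s)) for i, s in enumerate(sf) if s >= score_threshold]
    hits += [(int(i), "-", float(s)) for i, s in enumerate(sr) if s >= score_threshold]
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    su, sv = u.std(), v.std()
    if su == 0.0 and sv == 0.0:
        return 1.0 if np.allclose(u, v) else 0.0
    if su == 0.0 or sv == 0.0:
        return 0.0
    return float(np.corrcoef(u, v)[0, 1])


def _rc_freqs(freqs: np.ndarray) -> np.ndarray:
    return freqs[::-1, ::-1]


def compare_motifs(
    a: Motif, b: Motif, min_overlap: int = 5
) -> tuple[int, str, float]:
    """Best (offset, orientation, mean per-column Pearson r) over all
    alignments of b against a with >= min_overlap columns; orientation is
    'forward' or 'reverse' (b reverse-complemented). Offset is the position of
    b's first column relative to a's first column."""
    fa = a.frequencies
    results = []
    for orientation, fb in (("forward", b.frequencies), ("reverse", _rc_freqs(b.frequencies))):
        wa, wb = fa.shape[0], fb.shape[0]
        for offset in range(-(wb - min_overlap), wa - min_overlap + 1):
            cols_a = range(max(0, offset), min(wa, offset + wb))
            if len(cols_a) < min_overlap:
                continue
            corr = float(
                np.mean([_pearson(fa[j], fb[j - offset]) for j in cols_a])
            )
            results.append((corr, orientation == "forward", -abs(offset), offset, orientation))
    if not results:
        raise ValueError("no alignment satisfies min_overlap")
    best = max(results)
    return best[3], best[4], best[0]


def write_meme_minimal(
    motifs: dict[str, Motif], path, background: np.ndarray | None = None
) -> None:
    """MEME minimal motif format (version header + letter-probability matrices)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = np.full(4, 0.25) if background is None else background
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {p:.4f}" for b, p in zip(BASES, bg)) + "\n\n")
        for name, m in motifs.items():
            totals = m.counts.sum(axis=1, keepdims=True)
            p = (m.counts + m.pseudocount) / (totals + 4 * m.pseudocount)
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= {m.n_sites} E= 0\n"
            )
            for row in p:
                fh.write(" " + " ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")
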