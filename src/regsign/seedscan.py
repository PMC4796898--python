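"""Seed-match scanning and hypergeometric word-enrichment landscapes.

A microRNA recognises targets chiefly through its *seed* (nucleotides 2-8
of the mature sequence); a 3'UTR carrying the reverse-complement DNA
heptamer of the seed is a candidate target.  Given a gene list ranked from
most up- to most downregulated, the landscape statistic asks, at each
leading-bin cutoff, whether genes whose UTR contains a given heptamer are
over- or under-represented among the leading genes, using the exact
hypergeometric tail on per-gene presence/absence calls.

Scoring is presence/absence per gene (one count no matter how many sites)
— the simplest exact urn model.  This deliberately omits the
composition-bias corrections of word-counting tools; see the methods note.

Scores are signed: -log10(p) of the enrichment tail when enrichment is the
stronger signal (positive peaks = enriched among upregulated genes), and
+log10(p) of the depletion tail otherwise (negative peaks = depleted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

WORD_LEN = 7
_DNA = "ACGT"
_CODE = {c: i for i, c in enumerate(_DNA)}
_RNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "U": "A"}
_MIN_P = 1e-300  # guard against log10(0) at extreme enrichment


@dataclass
class RankedUtrSet:
    """Genes ordered most-upregulated first, each with its 3'UTR sequence.

    Genes with UTRs shorter than one word are retained (they simply never
    carry a word) and flagged in ``short_genes``.
    """

    genes: list[str]
    sequences: dict[str, str]
    short_genes: list[str] = field(init=False)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene ranking contains duplicates")
        missing = [g for g in self.genes if g not in self.sequences]
        if missing:
            raise ValueError(f"genes without sequence: {missing[:5]}")
        self.sequences = {g: s.upper() for g, s in self.sequences.items()}
        self.short_genes = [g for g in self.genes if len(self.sequences[g]) < WORD_LEN]

    def __len__(self) -> int:
        return len(self.genes)


def seed_to_match(mature: str) -> str:
    """DNA heptamer complementary to a mature microRNA's seed region.

    The seed is nucleotides 2-8 (1-based) of the mature RNA; the match
    motif searched for in 3'UTRs is its reverse complement in DNA.
    """
    seq = mature.upper()
    if any(c not in "ACGU" for c in seq):
        bad = sorted({c for c in seq if c not in "ACGU"})
        raise ValueError(f"mature sequence must be RNA (ACGU); found {bad}")
    if len(seq) < 8:
        raise ValueError(f"mature sequence too short for a seed (need >= 8 nt, got {len(seq)})")
    seed = seq[1:8]
    return "".join(_RNA_COMPLEMENT[c] for c in reversed(seed))


def seed_match_sites(utr: str, motif: str) -> list[int]:
    """All exact (possibly overlapping) motif occurrences, 0-based starts.

    Forward strand only: UTRs are supplied sense-strand and the motif is
    already the reverse complement of the seed.
    """
    if len(motif) != WORD_LEN:
        raise ValueError(f"motif must be {WORD_LEN} nt, got {len(motif)}")
    motif = motif.upper()
    if any(c not in _DNA for c in motif):
        raise ValueError(f"motif must be unambiguous DNA (ACGT): {motif!r}")
    utr = utr.upper()
    sites, start = [], 0
    while True:
        i = utr.find(motif, start)
        if i < 0:
            return sites
        sites.append(i)
        start = i + 1


@dataclass
class WordLandscape:
    """Signed significance profile of one word along the ranking."""

    word: str
    cutoffs: np.ndarray
    scores: np.ndarray
    p_enrich: np.ndarray
    p_deplete: np.ndarray
    n_genes: int
    n_present: int

    @property
    def peak_score(self) -> float:
        return float(self.scores[np.argmax(np.abs(self.scores))])

    @property
    def peak_cutoff(self) -> int:
        return int(self.cutoffs[np.argmax(np.abs(self.scores))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "word": self.word,
                "cutoff": self.cutoffs,
                "score": self.scores,
                "p_enrich": self.p_enrich,
                "p_deplete": self.p_deplete,
            }
        )


def default_bin_step(n_genes: int) -> int:
    """About 50 landscape points across the ranking."""
    return max(1, n_genes // 50)


def _cutoffs(n: int, bin_step: int) -> np.ndarray:
    if bin_step < 1:
        raise ValueError("bin_step must be >= 1")
    return np.arange(bin_step, n + 1, bin_step, dtype=int)


def _signed_scores(k: np.ndarray, N: int, K, c) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised signed scores from leading-bin presence counts ``k``.

    The exact tails are evaluated once per distinct (k, K, c) triple —
    across 4^7 words the triples repeat heavily, which keeps the full
    heptamer scan fast without approximating anything.
    """
    k, K, c = np.broadcast_arrays(k, K, c)
    key = (c.astype(np.int64) * (N + 1) + K) * (N + 1) + k
    uniq, inv = np.unique(key, return_inverse=True)
    ku = uniq % (N + 1)
    Ku = (uniq // (N + 1)) % (N + 1)
    cu = uniq // ((N + 1) * (N + 1))
    p_enr = np.clip(stats.hypergeom.sf(ku - 1, N, Ku, cu)[inv].reshape(k.shape), _MIN_P, 1.0)
    p_dep = np.clip(stats.hypergeom.cdf(ku, N, Ku, cu)[inv].reshape(k.shape), _MIN_P, 1.0)
    scores = np.where(p_enr <= p_dep, -np.log10(p_enr), np.log10(p_dep))
    return scores, p_enr, p_dep


def word_landscape(ranked: RankedUtrSet, word: str, bin_step: int | None = None) -> WordLandscape:
    """Hypergeometric enrichment/depletion profile of one heptamer.

    At each cutoff c the leading c genes form the drawn sample; k of them
    carry the word, K of all N genes do.  The enrichment tail is
    P(X >= k), the depletion tail P(X <= k).
    """
    if len(word) != WORD_LEN:
        raise ValueError(f"word must be {WORD_LEN} nt, got {len(word)}")
    if any(c not in _DNA for c in word.upper()):
        raise ValueError(f"word must be unambiguous DNA: {word!r}")
    n = len(ranked)
    step = default_bin_step(n) if bin_step is None else bin_step
    cut = _cutoffs(n, step)
    present = np.array(
        [bool(seed_match_sites(ranked.sequences[g], word)) for g in ranked.genes], dtype=bool
    )
    K = int(present.sum())
    k = np.cumsum(present)[cut - 1]
    scores, p_enr, p_dep = _signed_scores(k, n, K, cut)
    return WordLandscape(word.upper(), cut, scores, p_enr, p_dep, n_genes=n, n_present=K)


def _encode(seq: str) -> np.ndarray:
    """Base codes (A=0,C=1,G=2,T=3); anything else becomes -1."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int64)
    for c, i in _CODE.items():
        lut[ord(c)] = i
    return lut[arr]


def words_present(seq: str) -> np.ndarray:
    """Codes (base-4 integers) of all distinct heptamers in one sequence."""
    codes = _encode(seq.upper())
    L = codes.size
    if L < WORD_LEN:
        return np.empty(0, dtype=np.int64)
    n_win = L - WORD_LEN + 1
    vals = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    for j in range(WORD_LEN):
        window = codes[j : j + n_win]
        vals = vals * 4 + np.where(window >= 0, window, 0)
        valid &= window >= 0
    return np.unique(vals[valid])


def decode_word(code: int) -> str:
    out = []
    for _ in range(WORD_LEN):
        out.append(_DNA[code % 4])
        code //= 4
    return "".join(reversed(out))


def top_words(
    ranked: RankedUtrSet,
    n_words: int = 10,
    bin_step: int | None = None,
    words: list[str] | None = None,
) -> pd.DataFrame:
    """Rank heptamers by the peak |score| of their landscapes.

    Evaluates all 4^7 heptamers by default (or a user-restricted list) and
    returns the ``n_words`` strongest with their peak cutoff and sign.
    """
    n = len(ranked)
    step = default_bin_step(n) if bin_step is None else bin_step
    cut = _cutoffs(n, step)
    if n_words <= 0:
        return pd.DataFrame(columns=["word", "peak_score", "peak_cutoff", "n_present"])

    n_codes = 4**WORD_LEN
    presence = np.zeros((n, n_codes), dtype=bool)
    for i, g in enumerate(ranked.genes):
        presence[i, words_present(ranked.sequences[g])] = True
    if words is not None:
        sel = np.array(sorted({_word_code(w) for w in words}), dtype=np.int64)
    else:
        sel = np.arange(n_codes, dtype=np.int64)
    presence = presence[:, sel]
    cum = np.cumsum(presence, axis=0)
    K = cum[-1]
    k = cum[cut - 1]  # shape (n_cutoffs, n_sel)
    scores, _, _ = _signed_scores(k, n, K[None, :], cut[:, None])
    peak_idx = np.argmax(np.abs(scores), axis=0)
    word_idx = np.arange(sel.size)
    peak_scores = scores[peak_idx, word_idx]
    order = np.lexsort((sel, -np.abs(peak_scores)))[:n_words]
    return pd.DataFrame(
        {
            "word": [decode_word(int(sel[i])) for i in order],
            "peak_score": peak_scores[order],
            "peak_cutoff": cut[peak_idx[order]],
            "n_present": K[order],
        }
    )


def _word_code(word: str) -> int:
    if len(word) != WORD_LEN or any(c not in _DNA for c in word.upper()):
        raise ValueError(f"invalid heptamer {word!r}")
    code = 0
    for c in word.upper():
        code = code * 4 + _CODE[c]
    return code
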