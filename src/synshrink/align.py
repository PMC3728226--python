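"""Protein-vs-DNA local alignment without external search binaries.

The scorer mimics a translated search (TBLASTN-style): the DNA subject is
translated in all six frames, exact amino-acid k-mer seeds locate candidate
diagonals, and a window-restricted Smith-Waterman with affine gaps scores
each candidate on the protein level. Alignment coordinates are mapped back
to DNA space (0-based half-open, forward strand; reverse-strand hits carry
``subject_reversed=True``).

Scores are raw substitution-matrix scores; no e-value statistics are
computed. Downstream modules treat ``score >= min_report_score`` as
significant when this scorer is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .io import HitRecord, ParameterError, revcomp

__all__ = [
    "ScoringScheme",
    "translate",
    "translate_dna",
    "smith_waterman",
    "seeded_local_align",
    "TranslatedSearchIndex",
]

_AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = {c: i for i, c in enumerate(_AA_ALPHABET)}
_NALPHA = len(_AA_ALPHABET)


def _load_blosum62() -> np.ndarray:
    m = substitution_matrices.load("BLOSUM62")
    out = np.zeros((_NALPHA, _NALPHA), dtype=np.int32)
    for i, a in enumerate(_AA_ALPHABET):
        for j, b in enumerate(_AA_ALPHABET):
            out[i, j] = int(m[a, b])
    return out


@dataclass
class ScoringScheme:
    """Substitution matrix plus affine gap model.

    A gap of length L costs ``gap_open + L * gap_extend`` (both negative).
    ``min_report_score`` is the significance cutoff used when no e-value is
    available. ``seed_k`` is the exact amino-acid seed length and ``band``
    the half-width (in residues) of the window around a seed cluster inside
    which the dynamic programming runs.
    """

    matrix: np.ndarray = field(default_factory=_load_blosum62)
    matrix_name: str = "BLOSUM62"
    gap_open: int = -10
    gap_extend: int = -1
    min_report_score: int = 50
    seed_k: int = 4
    band: int = 32

    def __post_init__(self) -> None:
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ParameterError("gap penalties must be negative")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ParameterError("substitution matrix must be symmetric")


def encode_protein(protein: str) -> np.ndarray:
    """Protein string -> array of alphabet indices (unknowns become X)."""
    x = _AA_INDEX["X"]
    return np.fromiter((_AA_INDEX.get(c, x) for c in protein), dtype=np.int64, count=len(protein))


def translate_dna(dna: str) -> str:
    """Translate a forward-frame DNA string; trailing partial codon dropped,
    internal stops emitted as '*'."""
    usable = len(dna) - len(dna) % 3
    if usable == 0:
        return ""
    return str(Seq(dna[:usable]).translate())


def translate(dna: str, frame: int, strand: str = "+") -> str:
    """Translate one of the six reading frames of ``dna``."""
    if frame not in (0, 1, 2):
        raise ParameterError(f"frame must be 0, 1 or 2, got {frame}")
    if strand not in ("+", "-"):
        raise ParameterError(f"strand must be + or -, got {strand}")
    seq = dna if strand == "+" else revcomp(dna)
    return translate_dna(seq[frame:])


# ---------------------------------------------------------------------------
# Smith-Waterman (affine gaps, row-vectorised)
# ---------------------------------------------------------------------------

_NEG = -(10 ** 9)


def smith_waterman(
    query: str | np.ndarray, subject: str | np.ndarray, scheme: ScoringScheme
) -> tuple[int, tuple[int, int], tuple[int, int]]:
    """Best local alignment of two protein strings.

    Returns ``(score, (q_start, q_end), (s_start, s_end))`` with half-open
    intervals; score 0 with empty intervals when nothing aligns positively.

    Within-row gap dependencies are resolved exactly with a prefix-max scan:
    a horizontal gap run always starts from a cell that did not itself end
    in a horizontal gap, so E can be expanded linearly over those cells.
    """
    q = encode_protein(query) if isinstance(query, str) else query
    s = encode_protein(subject) if isinstance(subject, str) else subject
    m, n = len(q), len(s)
    if m == 0 or n == 0:
        return 0, (0, 0), (0, 0)
    go, ge = scheme.gap_open, scheme.gap_extend
    sub = scheme.matrix

    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    F = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    idx = np.arange(1, n + 1, dtype=np.int64)

    for i in range(1, m + 1):
        srow = sub[q[i - 1], s]
        F[i, 1:] = np.maximum(F[i - 1, 1:] + ge, H[i - 1, 1:] + go + ge)
        h_pre = np.maximum(H[i - 1, :-1] + srow, F[i, 1:])
        np.maximum(h_pre, 0, out=h_pre)
        # E[j] = go + ge*(j-k) + H_pre[k] maximised over k < j
        t = h_pre - ge * idx
        run = np.maximum.accumulate(t)
        e = np.empty(n, dtype=np.int64)
        e[0] = _NEG
        e[1:] = run[:-1] + ge * idx[1:] + go
        H[i, 1:] = np.maximum(h_pre, e)

    best = int(H.max())
    if best <= 0:
        return 0, (0, 0), (0, 0)
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    q_end, s_end = int(i), int(j)

    # traceback on recomputed local decisions
    i, j = q_end, s_end
    while i > 0 and j > 0 and H[i, j] > 0:
        h = H[i, j]
        if h == H[i - 1, j - 1] + sub[q[i - 1], s[j - 1]]:
            i, j = i - 1, j - 1
            continue
        # vertical gap run ending here?
        if h == F[i, j]:
            k = i
            while k > 1 and F[k, j] == F[k - 1, j] + ge:
                k -= 1
            i = k - 1
            continue
        # horizontal gap: find the opener k with H[i,k] + go + ge*(j-k) == h
        moved = False
        for k in range(j - 1, 0, -1):
            if H[i, k] + go + ge * (j - k) == h:
                j = k
                moved = True
                break
        if not moved:  # numerical fallback; should not happen
            i, j = i - 1, j - 1
    return best, (i, q_end), (j, s_end)


# ---------------------------------------------------------------------------
# seeded six-frame search
# ---------------------------------------------------------------------------

def _kmer_codes(encoded: np.ndarray, k: int) -> np.ndarray:
    """Rolling k-mer codes over an encoded protein; -1 where the window
    contains an X or stop (those never seed)."""
    n = len(encoded) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    x, stop = _AA_INDEX["X"], _AA_INDEX["*"]
    for off in range(k):
        w = encoded[off : off + n]
        codes = codes * _NALPHA + w
        bad |= (w == x) | (w == stop)
    codes[bad] = -1
    return codes


class TranslatedSearchIndex:
    """Seed index over the six-frame translations of a set of DNA subjects.

    Build once per genome, then :meth:`search` each protein query against it.
    """

    def __init__(self, subjects: list[tuple[str, str]], scheme: ScoringScheme | None = None,
                 max_seed_occurrences: int = 500, max_clusters: int = 50,
                 min_cluster_seeds: int = 3):
        self.scheme = scheme or ScoringScheme()
        self.max_seed_occurrences = max_seed_occurrences
        self.max_clusters = max_clusters
        # isolated chance seeds are not extended; a real homolog at the
        # divergences this scorer targets seeds a diagonal many times
        self.min_cluster_seeds = min_cluster_seeds
        self.frames: list[tuple[str, str, int, np.ndarray, int]] = []
        # per frame: (subject_id, strand, frame_offset, encoded protein, dna_length)
        code_chunks, fid_chunks, pos_chunks = [], [], []
        k = self.scheme.seed_k
        for sid, dna in subjects:
            for strand in ("+", "-"):
                for f in range(3):
                    prot = translate(dna, f, strand)
                    enc = encode_protein(prot)
                    fid = len(self.frames)
                    self.frames.append((sid, strand, f, enc, len(dna)))
                    codes = _kmer_codes(enc, k)
                    keep = codes >= 0
                    if keep.any():
                        code_chunks.append(codes[keep])
                        pos_chunks.append(np.nonzero(keep)[0])
                        fid_chunks.append(np.full(int(keep.sum()), fid, dtype=np.int64))
        if code_chunks:
            codes = np.concatenate(code_chunks)
            order = np.argsort(codes, kind="stable")
            self._codes = codes[order]
            self._pos = np.concatenate(pos_chunks)[order]
            self._fid = np.concatenate(fid_chunks)[order]
        else:
            self._codes = np.empty(0, dtype=np.int64)
            self._pos = np.empty(0, dtype=np.int64)
            self._fid = np.empty(0, dtype=np.int64)

    def search(self, protein: str, query_id: str = "query") -> list[HitRecord]:
        """All hits of one protein query, best-first, score >= min_report_score."""
        scheme = self.scheme
        k = scheme.seed_k
        enc_q = encode_protein(protein)
        qcodes = _kmer_codes(enc_q, k)
        seeds: dict[int, list[tuple[int, int]]] = {}
        for qpos, code in enumerate(qcodes):
            if code < 0:
                continue
            lo = np.searchsorted(self._codes, code, side="left")
            hi = np.searchsorted(self._codes, code, side="right")
            if hi - lo == 0 or hi - lo > self.max_seed_occurrences:
                continue
            for fid, spos in zip(self._fid[lo:hi], self._pos[lo:hi]):
                seeds.setdefault(int(fid), []).append((int(spos), qpos))

        hits: list[HitRecord] = []
        for fid, fr_seeds in seeds.items():
            sid, strand, foff, enc_s, dna_len = self.frames[fid]
            # cluster by diagonal
            diags = sorted(set(sp - qp for sp, qp in fr_seeds))
            clusters: list[list[int]] = [[diags[0]]]
            for d in diags[1:]:
                if d - clusters[-1][-1] <= scheme.band:
                    clusters[-1].append(d)
                else:
                    clusters.append([d])
            n_seeds = {id(c): 0 for c in clusters}
            for sp, qp in fr_seeds:
                d = sp - qp
                for c in clusters:
                    if c[0] <= d <= c[-1]:
                        n_seeds[id(c)] += 1
                        break
            clusters = [c for c in clusters if n_seeds[id(c)] >= self.min_cluster_seeds]
            clusters.sort(key=lambda c: -n_seeds[id(c)])
            for c in clusters[: self.max_clusters]:
                w_lo = max(0, c[0] - scheme.band)
                w_hi = min(len(enc_s), c[-1] + len(enc_q) + scheme.band)
                if w_hi <= w_lo:
                    continue
                score, (qa, qb), (sa, sb) = smith_waterman(enc_q, enc_s[w_lo:w_hi], scheme)
                if score < scheme.min_report_score:
                    continue
                pa, pb = sa + w_lo, sb + w_lo  # protein coords within frame
                if strand == "+":
                    da, db = foff + 3 * pa, foff + 3 * pb
                    rev = False
                else:
                    da, db = dna_len - (foff + 3 * pb), dna_len - (foff + 3 * pa)
                    rev = True
                hits.append(
                    HitRecord(
                        query_id=query_id,
                        subject_id=sid,
                        score=float(score),
                        significance=0.0,
                        query_interval=(qa, qb),
                        subject_interval=(da, db),
                        subject_reversed=rev,
                    )
                )
        hits.sort(key=lambda h: (-h.score, h.subject_id, h.subject_interval))
        return hits


def seeded_local_align(query: str, subject: str, scheme: ScoringScheme | None = None,
                       query_id: str = "query", subject_id: str = "subject") -> list[HitRecord]:
    """Align one protein query against one DNA subject in all six frames.

    Thin convenience wrapper over :class:`TranslatedSearchIndex` for a single
    subject; returns hits best-first (possibly empty).
    """
    if len(subject) < 3:
        return []
    index = TranslatedSearchIndex([(subject_id, subject)], scheme)
    return index.search(query, query_id=query_id)
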