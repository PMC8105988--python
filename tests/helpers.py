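"""Independent brute-force oracles used to verify the implementation."""
from __future__ import annotations

import numpy as np

from pymocca.motifs import IUPAC_CODES, reverse_complement_iupac


def naive_scan(motifs, seq: str, both_strands: bool = True):
    """Per-motif, per-position Hamming-tolerant IUPAC matcher.

    A sequence N disqualifies the window outright (it is not a mismatch).
    Returns a set of (motif name, start, end, strand) tuples; a motif equal
    to its own reverse complement is reported on '+' only.
    """
    out = set()
    for m in motifs:
        patterns = [(m.pattern, "+")]
        rc = reverse_complement_iupac(m.pattern)
        if both_strands and rc != m.pattern:
            patterns.append((rc, "-"))
        for pattern, strand in patterns:
            L = len(pattern)
            for s in range(len(seq) - L + 1):
                mismatches = 0
                ok = True
                for a, b in zip(seq[s : s + L], pattern):
                    if a == "N":
                        ok = False
                        break
                    if a not in IUPAC_CODES[b]:
                        mismatches += 1
                        if mismatches > m.mismatches:
                            ok = False
                            break
                if ok:
                    out.add((m.name, s, s + L, strand))
    return out


def brute_average_precision(y, scores) -> float:
    """Step-wise average precision over all unique score thresholds."""
    y = np.asarray(y, dtype=bool)
    s = np.asarray(scores, dtype=float)
    n_pos = y.sum()
    ap = 0.0
    prev_recall = 0.0
    for t in sorted(np.unique(s), reverse=True):
        tp = (y & (s >= t)).sum()
        fp = (~y & (s >= t)).sum()
        precision = tp / (tp + fp)
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return float(ap)


def brute_roc_auc(y, scores) -> float:
    """Mann-Whitney pair counting with ties scored one half."""
    y = np.asarray(y, dtype=bool)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y], s[~y]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins / (len(pos) * len(neg)))


def brute_pair_counts(occs, cutoff: float) -> dict[tuple[str, str], int]:
    """Double loop over all unordered occurrence pairs within the cutoff."""
    counts: dict[tuple[str, str], int] = {}
    items = list(occs)
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            a, b = items[i], items[j]
            if abs(a.center - b.center) <= cutoff:
                key = tuple(sorted((a.motif, b.motif)))
                counts[key] = counts.get(key, 0) + 1
    return counts


def random_iupac_motifs(rng: np.random.Generator, n_max: int = 8):
    """Random degenerate motif sets for FSM/oracle equivalence trials."""
    from pymocca.motifs import IupacMotif

    letters = list(IUPAC_CODES)
    motifs = []
    for i in range(int(rng.integers(1, n_max + 1))):
        length = int(rng.integers(3, 13))
        # bias towards concrete bases so that matches stay informative
        pattern = "".join(
            letters[int(rng.integers(4))] if rng.random() < 0.7
            else letters[int(rng.integers(len(letters)))]
            for _ in range(length)
        )
        mm = int(rng.integers(0, 2)) if length >= 6 else 0
        motifs.append(IupacMotif(f"m{i}", pattern, mm))
    return motifs
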