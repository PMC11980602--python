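"""Independent brute-force oracles used to cross-check the library.

These deliberately share no code with defdyn: direct formulas and naive
enumeration only.
"""

from __future__ import annotations

_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def bray_curtis_direct(x, y) -> float:
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return 1.0 - num / den


def rpkm_direct(count: float, length_bp: int, total_reads: int) -> float:
    return count / (length_bp / 1000.0) / (total_reads / 1e6)


def brute_force_match(spacer_seqs, votus: dict[str, str],
                      max_mismatches: int = 1,
                      min_identity: float = 95.0) -> set[tuple]:
    """Sliding-window enumeration of every full-length ungapped alignment
    of every spacer (both strands) against every vOTU window.

    Returns tuples (spacer, votu_id, position, strand, mismatches).
    """
    hits = set()
    for spacer in set(spacer_seqs):
        length = len(spacer)
        allowed = min(max_mismatches,
                      int(length * (1.0 - min_identity / 100.0) + 1e-9))
        for strand, query in (("+", spacer), ("-", revcomp(spacer))):
            for votu_id, seq in votus.items():
                for pos in range(len(seq) - length + 1):
                    mm = 0
                    for i in range(length):
                        if seq[pos + i] != query[i]:
                            mm += 1
                            if mm > allowed:
                                break
                    else:
                        hits.add((spacer, votu_id, pos, strand, mm))
    return hits
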