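"""Cytosine sequence-context classification (CG / CHG / CHH).

In plant genomes methylation is tracked in three sequence contexts defined
by the two bases 3' of each cytosine: CG, CHG and CHH, where H is A, C or T.
CG and CHG are strand-symmetric (a plus-strand CG at position i pairs with a
minus-strand CG at i+1; CHG pairs at i+2), CHH is not. Every cytosine on the
plus strand and every guanine on the plus strand (a cytosine on the minus
strand) receives exactly one label; cytosines whose downstream context runs
off the chromosome end or touches a non-ACGT base are labelled AMBIGUOUS and
excluded from statistics.

Coordinates are 1-based inclusive throughout, matching the convention of
per-cytosine count tables; soft-masked (lower-case) bases are classified
normally.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")
AMBIGUOUS = "AMBIGUOUS"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def classify_cytosine(sequence: str, position: int, strand: str) -> str:
    """Context label of the cytosine at ``position`` (1-based) on ``strand``.

    On the plus strand the site must be a C; on the minus strand the plus
    sequence shows a G there. The label is CG if the next base 3' (on the
    site's own strand) is G, CHG if the base after next is G, CHH if both
    are in {A, C, T}; AMBIGUOUS when the needed bases fall off the sequence
    end or are not plain A/C/G/T.

    Raises
    ------
    ValueError
        if ``position`` does not hold a cytosine on the requested strand.
    """
    seq = sequence.upper()
    n = len(seq)
    i = position - 1
    if i < 0 or i >= n:
        raise ValueError(f"position {position} outside sequence of length {n}")
    if strand == "+":
        if seq[i] != "C":
            raise ValueError(f"position {position} (+) is {seq[i]!r}, not C")
        nxt = seq[i + 1] if i + 1 < n else None
        nxt2 = seq[i + 2] if i + 2 < n else None
    elif strand == "-":
        if seq[i] != "G":
            raise ValueError(f"position {position} (-) is {seq[i]!r}, not C")
        nxt = seq[i - 1].translate(_COMPLEMENT) if i - 1 >= 0 else None
        nxt2 = seq[i - 2].translate(_COMPLEMENT) if i - 2 >= 0 else None
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")

    if nxt is None:
        return AMBIGUOUS
    if nxt == "G":
        return "CG"
    if nxt not in "ACT":
        return AMBIGUOUS
    if nxt2 is None:
        return AMBIGUOUS
    if nxt2 == "G":
        return "CHG"
    if nxt2 in "ACT":
        return "CHH"
    return AMBIGUOUS


def _classify_plus_strand(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised plus-strand classification over a byte-code array.

    ``codes`` holds uint8 ASCII of the upper-cased sequence. Returns
    (positions 0-based, labels) for every C in the array.
    """
    n = codes.size
    C, G = ord("C"), ord("G")
    acgt = np.isin(codes, np.frombuffer(b"ACGT", dtype=np.uint8))
    is_c = codes == C
    pos = np.nonzero(is_c)[0]
    labels = np.full(pos.size, AMBIGUOUS, dtype=object)

    nxt = np.full(pos.size, 0, dtype=np.uint8)
    has_nxt = pos + 1 < n
    nxt[has_nxt] = codes[pos[has_nxt] + 1]
    nxt_ok = np.zeros(pos.size, dtype=bool)
    nxt_ok[has_nxt] = acgt[pos[has_nxt] + 1]

    nxt2 = np.full(pos.size, 0, dtype=np.uint8)
    has_nxt2 = pos + 2 < n
    nxt2[has_nxt2] = codes[pos[has_nxt2] + 2]
    nxt2_ok = np.zeros(pos.size, dtype=bool)
    nxt2_ok[has_nxt2] = acgt[pos[has_nxt2] + 2]

    labels[has_nxt & (nxt == G)] = "CG"
    h1 = has_nxt & nxt_ok & (nxt != G)  # first downstream base is H
    labels[h1 & has_nxt2 & (nxt2 == G)] = "CHG"
    labels[h1 & has_nxt2 & nxt2_ok & (nxt2 != G)] = "CHH"
    return pos, labels


def classify_sequence(sequence: str) -> pd.DataFrame:
    """Classify every cytosine on both strands of one sequence.

    Returns a DataFrame with columns ``pos`` (1-based), ``strand`` and
    ``context``, sorted by position then strand.
    """
    seq = sequence.upper()
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    plus_pos, plus_lab = _classify_plus_strand(codes)

    # minus strand: classify the reverse complement, then mirror coordinates
    rc = reverse_complement(seq)
    rc_codes = np.frombuffer(rc.encode("ascii"), dtype=np.uint8)
    rc_pos, minus_lab = _classify_plus_strand(rc_codes)
    minus_pos = codes.size - 1 - rc_pos  # 0-based position on plus sequence

    df = pd.DataFrame(
        {
            "pos": np.concatenate([plus_pos, minus_pos]) + 1,
            "strand": np.repeat(["+", "-"], [plus_pos.size, minus_pos.size]),
            "context": np.concatenate([plus_lab, minus_lab]),
        }
    )
    return df.sort_values(["pos", "strand"], kind="stable", ignore_index=True)


def build_context_index(genome: dict[str, str]) -> pd.DataFrame:
    """Classify every cytosine of a genome given as {chromosome: sequence}.

    Returns the context index: columns ``chrom``, ``pos`` (1-based),
    ``strand``, ``context`` with context in {CG, CHG, CHH, AMBIGUOUS}.
    An empty genome yields an empty index.
    """
    parts = []
    for chrom, seq in genome.items():
        if not seq:
            continue
        df = classify_sequence(seq)
        df.insert(0, "chrom", chrom)
        parts.append(df)
    if not parts:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context"])
    return pd.concat(parts, ignore_index=True)


def context_counts(index: pd.DataFrame) -> pd.Series:
    """Number of sites per context label over both strands."""
    return index["context"].value_counts()
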