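"""Mismatch-tolerant genomic off-target enumeration with PAM constraint.

Sites are near-matches to a protospacer on either strand: Hamming
distance only (no bulges), with the 3'-adjacent PAM required to match
an IUPAC pattern exactly (PAM mismatches are never counted).  The
"seed" is the PAM-proximal stretch of the protospacer (12 bp by field
convention) where mismatches most strongly disrupt targeting.

The scan is a vectorised sliding-window comparison over each contig;
its normative reference is a position-by-position brute-force Hamming
oracle (exercised in the test suite).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .seqcore import GenomeIndex, IUPAC_EXPANSION, reverse_complement

DEFAULT_SEED_LENGTH = 12

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
# Everything outside ACGT (N and degenerate codes) encodes to 4: it
# mismatches every guide base and fails every concrete PAM position.
_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _v in _CODE.items():
    _ENCODE_LUT[ord(_b)] = _v


def _encode(seq: str) -> np.ndarray:
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _pam_mask(codes: np.ndarray, pattern: str, length: int) -> np.ndarray:
    """Boolean array over window start offsets: does the PAM starting at
    offset+length match *pattern*?  Ambiguous genome bases only satisfy
    pattern N."""
    n = codes.size
    k = len(pattern)
    starts = n - length - k + 1
    if starts <= 0:
        return np.zeros(0, dtype=bool)
    mask = np.ones(starts, dtype=bool)
    for j, pbase in enumerate(pattern):
        allowed = IUPAC_EXPANSION[pbase]
        ok = np.zeros(5, dtype=bool)
        for b in allowed:
            ok[_CODE[b]] = True
        if pbase == "N":
            ok[4] = True  # genome N satisfies pattern N only
        mask &= ok[codes[length + j:length + j + starts]]
    return mask


@dataclass(frozen=True)
class OffTargetSite:
    chrom: str
    strand: str
    genomic_start: int  # 1-based coordinate of the protospacer 5' base
    site_sequence: str
    pam_observed: str
    mismatch_count: int
    mismatch_positions: tuple[int, ...]  # ascending, 1-based protospacer
    seed_identical: bool

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.genomic_start, self.strand)


def _scan_strand(contig_name: str, seq: str, strand: str, guide: str,
                 pam_pattern: str, max_mismatch: int,
                 seed_length: int, seed_exact_only: bool,
                 contig_length: int) -> list[OffTargetSite]:
    L = len(guide)
    k = len(pam_pattern)
    codes = _encode(seq)
    if codes.size < L + k:
        return []
    guide_codes = _encode(guide)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    starts = codes.size - L - k + 1
    windows = windows[:starts]
    mism = windows != guide_codes
    counts = mism.sum(axis=1)
    pam_ok = _pam_mask(codes, pam_pattern, L)
    if seed_exact_only:
        seed_ok = ~mism[:, L - seed_length:].any(axis=1)
        hit = pam_ok & seed_ok
    else:
        hit = pam_ok & (counts <= max_mismatch)
    sites = []
    for i in np.flatnonzero(hit):
        i = int(i)
        positions = tuple(int(p) + 1 for p in np.flatnonzero(mism[i]))
        seed_identical = not any(p >= L - seed_length + 1 for p in positions)
        if strand == "+":
            start = i + 1
        else:
            # offset i on the reverse-complemented axis: the protospacer
            # 5' base sits at forward coordinate (contig_length - i).
            start = contig_length - i
        sites.append(OffTargetSite(
            chrom=contig_name, strand=strand, genomic_start=start,
            site_sequence=seq[i:i + L],
            pam_observed=seq[i + L:i + L + k],
            mismatch_count=int(counts[i]),
            mismatch_positions=positions,
            seed_identical=seed_identical,
        ))
    return sites


def _validate_guide(protospacer: str) -> str:
    protospacer = protospacer.upper()
    if not protospacer or any(b not in "ACGT" for b in protospacer):
        raise ContractError(
            "protospacer must be a non-empty ACGT string "
            "(degenerate guides unsupported)"
        )
    return protospacer


def search(genome: GenomeIndex, protospacer: str, pam_pattern: str = "NGN",
           max_mismatch: int = 3,
           seed_length: int = DEFAULT_SEED_LENGTH) -> list[OffTargetSite]:
    """All sites on either strand within *max_mismatch* of the
    protospacer and carrying a pattern-matching 3' PAM.

    The on-target site itself (distance 0) is included when present.
    Results are deterministic: sorted by (chrom, start, strand), with
    duplicates removed by that key.
    """
    protospacer = _validate_guide(protospacer)
    if max_mismatch > len(protospacer):
        raise ContractError("max_mismatch exceeds protospacer length")
    return _search_impl(genome, protospacer, pam_pattern, max_mismatch,
                        seed_length, seed_exact_only=False)


def seed_matches(genome: GenomeIndex, protospacer: str,
                 seed_length: int = DEFAULT_SEED_LENGTH,
                 pam_pattern: str = "NGN") -> list[OffTargetSite]:
    """All sites whose PAM-proximal *seed_length* bases match exactly,
    with any number of mismatches outside the seed."""
    protospacer = _validate_guide(protospacer)
    if seed_length > len(protospacer):
        raise ContractError("seed_length exceeds protospacer length")
    return _search_impl(genome, protospacer, pam_pattern,
                        max_mismatch=len(protospacer),
                        seed_length=seed_length, seed_exact_only=True)


def _search_impl(genome: GenomeIndex, protospacer: str, pam_pattern: str,
                 max_mismatch: int, seed_length: int,
                 seed_exact_only: bool) -> list[OffTargetSite]:
    out: dict[tuple, OffTargetSite] = {}
    for name in genome.contigs:
        seq = genome[name]
        n = len(seq)
        for strand, s in (("+", seq), ("-", reverse_complement(seq))):
            for site in _scan_strand(name, s, strand, protospacer,
                                     pam_pattern, max_mismatch,
                                     seed_length, seed_exact_only, n):
                out.setdefault(site.key, site)
    return sorted(out.values(),
                  key=lambda s: (s.chrom, s.genomic_start, s.strand))


def mismatch_histogram(sites: list[OffTargetSite]) -> dict[int, int]:
    """Map mismatch count -> number of sites; counts partition the list."""
    return dict(sorted(Counter(s.mismatch_count for s in sites).items()))
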