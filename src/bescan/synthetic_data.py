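"""Seeded generators for every input the pipeline consumes.

Each generator is deterministic under a fixed seed, emits a
machine-readable :class:`GroundTruth` describing exactly what was
planted, and re-verifies its own planting with an independent
brute-force check before returning.  Together they let every analysis
stage run end to end with no external downloads.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from .amplicon_quant import AmpliconSpec
from .design_scan import EditorProfile
from .errors import BescanError, ContractError
from .seqcore import GenomeIndex, VariantRecord, iupac_match, \
    reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class GenerationError(BescanError):
    """Planting failed after bounded retries."""


@dataclass
class GroundTruth:
    """What a generator planted, with the seed and parameters needed to
    recompute every expected output without rerunning generation."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)
    planted: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, default=_json_default)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def gen_genome(seed: int, length: int, gc_fraction: float = 0.42,
               name: str = "chrS") -> GenomeIndex:
    """Random genome with the requested GC content (defaults to a
    mammalian-like 42%)."""
    if length < 1:
        raise ContractError("length must be >= 1")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ContractError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2
    gc = gc_fraction / 2
    draw = rng.choice(_BASES, size=length, p=[at, gc, gc, at])
    return GenomeIndex({name: draw.tobytes().decode("ascii")})


def _instantiate_pam(pattern: str, rng: np.random.Generator) -> str:
    from .seqcore import IUPAC_EXPANSION
    return "".join(
        b if b in "ACGT" else rng.choice(sorted(IUPAC_EXPANSION[b]))
        for b in pattern
    )


def _mutate(guide: str, positions: list[int],
            rng: np.random.Generator) -> str:
    out = list(guide)
    for p in positions:
        choices = [b for b in "ACGT" if b != guide[p - 1]]
        out[p - 1] = rng.choice(choices)
    return "".join(out)


def _brute_force_sites(seq: str, guide: str, pam_pattern: str,
                       max_mismatch: int) -> list[tuple[int, str, int]]:
    """Independent verifier: (1-based 5' coordinate, strand, distance)
    for every near-match with a matching PAM.

    Computes the Hamming distance at every position of both strands by
    accumulating per-offset base comparisons (no windowing machinery
    shared with the search module), then checks candidate PAMs
    character by character."""
    L, k = len(guide), len(pam_pattern)
    found = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        n = len(s)
        starts = n - L - k + 1
        if starts <= 0:
            continue
        arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
        dist = np.zeros(starts, dtype=np.int32)
        for j, b in enumerate(guide):
            dist += arr[j:j + starts] != ord(b)
        for i in np.flatnonzero(dist <= max_mismatch):
            i = int(i)
            pam = s[i + L:i + L + k]
            if any(c not in "ACGT" for c in pam) or \
                    not iupac_match(pam_pattern, pam):
                continue
            start = i + 1 if strand == "+" else len(seq) - i
            found.append((start, strand, int(dist[i])))
    return found


def plant_offtargets(genome: GenomeIndex, protospacer: str,
                     pam_pattern: str, distance_spec: dict[int, int],
                     seed: int, seed_region_mismatch: Optional[bool] = None,
                     seed_length: int = 12, max_retries: int = 50
                     ) -> tuple[GenomeIndex, GroundTruth]:
    """Overwrite non-overlapping loci of *genome* with near-matches of
    the protospacer at the exact Hamming distances requested.

    ``seed_region_mismatch`` forces (True) or forbids (False) mismatch
    positions inside the PAM-proximal seed.  The planting is verified
    by brute force: the returned genome contains exactly the planted
    sites within the maximum requested distance (accidental extra
    near-matches trigger a reseeded retry).
    """
    protospacer = protospacer.upper()
    L = len(protospacer)
    k = len(pam_pattern)
    max_d = max(distance_spec) if distance_spec else 0
    (name, original), = genome.contigs.items()

    for attempt in range(max_retries):
        rng = np.random.default_rng((seed, attempt))
        seq = list(original)
        n = len(seq)
        site_len = L + k
        margin = site_len + 2
        planted = []
        occupied: list[tuple[int, int]] = []
        ok = True
        for d in sorted(distance_spec):
            for _ in range(distance_spec[d]):
                placed = False
                for _try in range(200):
                    start0 = int(rng.integers(0, n - site_len))
                    if any(start0 < e + margin and s - margin < start0 +
                           site_len for s, e in occupied):
                        continue
                    strand = rng.choice(["+", "-"])
                    if seed_region_mismatch is True:
                        pool = list(range(L - seed_length + 1, L + 1))
                    elif seed_region_mismatch is False:
                        pool = list(range(1, L - seed_length + 1))
                    else:
                        pool = list(range(1, L + 1))
                    if d > len(pool):
                        raise ContractError(
                            "distance exceeds allowed mismatch positions")
                    positions = sorted(
                        int(p) for p in rng.choice(pool, size=d,
                                                   replace=False))
                    site = _mutate(protospacer, positions, rng)
                    pam = _instantiate_pam(pam_pattern, rng)
                    insert = site + pam
                    if strand == "-":
                        insert = reverse_complement(insert)
                    seq[start0:start0 + site_len] = insert
                    occupied.append((start0, start0 + site_len))
                    if strand == "+":
                        genomic_start = start0 + 1
                    else:
                        genomic_start = start0 + site_len
                    planted.append({
                        "genomic_start": genomic_start, "strand": strand,
                        "distance": d, "mismatch_positions": positions,
                        "site_sequence": site, "pam": pam,
                    })
                    placed = True
                    break
                if not placed:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        new_seq = "".join(seq)
        found = _brute_force_sites(new_seq, protospacer, pam_pattern, max_d)
        expected = sorted((p["genomic_start"], p["strand"], p["distance"])
                          for p in planted)
        if sorted(found) == expected:
            truth = GroundTruth(
                kind="offtargets", seed=seed,
                params={"protospacer": protospacer,
                        "pam_pattern": pam_pattern,
                        "distance_spec": {str(kk): v for kk, v
                                          in distance_spec.items()},
                        "seed_length": seed_length,
                        "attempt": attempt},
                planted=planted,
            )
            return GenomeIndex({name: new_seq}), truth
    raise GenerationError(
        f"could not plant {distance_spec} without accidental near-matches "
        f"after {max_retries} retries"
    )


#: untargetable planting categories
UNTARGETABLE_CATEGORIES = ("no_pam", "out_of_window", "non_a_allele")


def gen_variant_table(seed: int, n: int, targetable_fraction: float,
                      editor: EditorProfile,
                      genome: Optional[GenomeIndex] = None
                      ) -> tuple[GenomeIndex, list[VariantRecord], GroundTruth]:
    """A pathogenic-variant table with a known number of targetable
    entries.

    Exactly ``round(n * targetable_fraction)`` variants are planted
    with an in-window, PAM-satisfying design under *editor*; the rest
    are guaranteed untargetable (no PAM in the window-reachable flank,
    target adenine only reachable outside the window, or a non-adenine
    disease allele), with the category recorded per variant.

    Each variant's local context is fully overwritten so targetability
    is decided by construction; the generator re-verifies the PAM
    layout of every planted context before returning.
    """
    if not 0.0 <= targetable_fraction <= 1.0:
        raise ContractError("targetable_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    spacing = 80
    L = editor.protospacer_length
    lo, hi = editor.window
    if genome is None:
        genome = gen_genome(int(rng.integers(2**31)), spacing * (n + 2))
    (name, seq), = genome.contigs.items()
    seq = list(seq)
    n_target = round(n * targetable_fraction)

    # For a + strand target adenine at x with protospacer position p,
    # the PAM occupies genomic [x - p + L + 1, x - p + L + len(pam)].
    pattern = editor.pam_patterns[0]
    g_positions = [j for j, b in enumerate(pattern, start=1) if b != "N"]
    if not g_positions:
        raise ContractError("cannot plant against an all-N PAM pattern")

    variants: list[VariantRecord] = []
    truth_rows = []
    for i in range(n):
        x = spacing * (i + 1)  # 1-based variant position
        targetable = i < n_target
        # Fresh random context around the variant.
        ctx_lo = x - L - 4
        ctx_hi = x + L + 4
        for j in range(ctx_lo - 1, ctx_hi):
            seq[j] = "ACGT"[int(rng.integers(4))]

        def pam_coord(p: int, j: int) -> int:
            return x - p + L + j  # 1-based genomic coordinate

        if targetable:
            p = int(rng.integers(lo, hi + 1))
            pam = _instantiate_pam(pattern, rng)
            for j, b in enumerate(pattern, start=1):
                seq[pam_coord(p, j) - 1] = pam[j - 1]
            # Forbid PAMs for the other in-window placements so the
            # planted design is the only in-window one; keeps the
            # planting unambiguous.
            for q in range(lo, hi + 1):
                if q == p:
                    continue
                jj = g_positions[0]
                if pam_coord(q, jj) not in {pam_coord(p, j)
                                            for j in range(1, len(pattern) + 1)}:
                    seq[pam_coord(q, jj) - 1] = "A"
            ref = "G"
            alt = "A"
            category = "targetable"
            planted_position = p
        else:
            category = UNTARGETABLE_CATEGORIES[i % 3]
            planted_position = None
            if category == "non_a_allele":
                ref, alt = ("T", "G") if rng.random() < 0.5 else ("A", "C")
                # still scrub window PAMs for tidiness
                for q in range(lo, hi + 1):
                    for j in g_positions:
                        seq[pam_coord(q, j) - 1] = "A"
            else:
                ref, alt = "G", "A"
                for q in range(lo, hi + 1):
                    for j in g_positions:
                        seq[pam_coord(q, j) - 1] = "A"
                if category == "out_of_window":
                    p_out = hi + 2
                    pam = _instantiate_pam(pattern, rng)
                    for j in range(1, len(pattern) + 1):
                        seq[pam_coord(p_out, j) - 1] = pam[j - 1]
                    planted_position = p_out
        seq[x - 1] = ref
        variants.append(VariantRecord(
            chrom=name, pos=x, ref=ref, alt=alt,
            significance="pathogenic", gene=f"GENE{i}",
        ))
        truth_rows.append({
            "pos": x, "ref": ref, "alt": alt, "category": category,
            "target_position": planted_position,
        })

    new_genome = GenomeIndex({name: "".join(seq)})
    _verify_variant_planting(new_genome, variants, truth_rows, editor)
    truth = GroundTruth(
        kind="variant_table", seed=seed,
        params={"n": n, "targetable_fraction": targetable_fraction,
                "n_targetable": n_target, "editor": editor.name,
                "window": list(editor.window),
                "pam_patterns": list(editor.pam_patterns)},
        planted=truth_rows,
    )
    return new_genome, variants, truth


def _verify_variant_planting(genome: GenomeIndex,
                             variants: list[VariantRecord],
                             truth_rows: list[dict],
                             editor: EditorProfile) -> None:
    """Brute-force re-check: enumerate every placement covering the
    disease base on both strands and confirm in-window targetability
    matches each planted category."""
    (name, seq), = genome.contigs.items()
    L = editor.protospacer_length
    lo, hi = editor.window
    for v, row in zip(variants, truth_rows):
        mutant = seq[:v.pos - 1] + v.alt + seq[v.pos:]
        hits = []
        for p in range(1, L + 1):
            # + strand placement
            s = v.pos - (p - 1)
            if v.alt == "A" and s >= 1:
                for pat in editor.pam_patterns:
                    k = len(pat)
                    if s + L + k - 2 <= len(seq):
                        pam = mutant[s + L - 1:s + L - 1 + k]
                        if iupac_match(pat, pam):
                            hits.append(("+", p))
                            break
            e = v.pos + (p - 1)
            if v.alt == "T" and e <= len(seq):
                for pat in editor.pam_patterns:
                    k = len(pat)
                    if e - L - k >= 0:
                        pam = reverse_complement(mutant[e - L - k:e - L])
                        if iupac_match(pat, pam):
                            hits.append(("-", p))
                            break
        in_window = any(lo <= p <= hi for _, p in hits)
        expected = row["category"] == "targetable"
        if in_window != expected:
            raise GenerationError(
                f"planting verification failed at {name}:{v.pos} "
                f"({row['category']}): in_window={in_window}"
            )


def simulate_amplicon_reads(seed: int, spec: AmpliconSpec, n_reads: int,
                            per_position_rates: dict[int, float],
                            error_rate: float = 0.001,
                            quality: int = 37,
                            fastq_path=None
                            ) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Amplicon-length reads with independent per-read Bernoulli edits
    at the programmed protospacer positions (on the protospacer strand)
    and uniform sequencing error elsewhere.

    Returns (seq, phred_string) pairs plus the ground truth, which
    records the exact number of edits drawn at each position.
    """
    for p, r in per_position_rates.items():
        if not 0.0 <= r <= 1.0:
            raise ContractError(f"rate at position {p} outside [0, 1]")
        base = spec.protospacer[p - 1]
        if base not in ("A", "C"):
            raise ContractError(
                f"protospacer position {p} is {base}; only A (A->G) and "
                "C (C->T) edits can be programmed"
            )
    rng = np.random.default_rng(seed)
    amp = spec.reference
    n_pos = len(amp)
    codes = np.frombuffer(amp.encode("ascii"), dtype=np.uint8)
    matrix = np.tile(codes, (n_reads, 1))

    flip = spec.strand == "-"
    edit_counts: dict[int, int] = {}
    edited_cols = set()
    for p, rate in per_position_rates.items():
        g = spec.amplicon_index(p)
        edited_cols.add(g)
        ref = spec.protospacer[p - 1]
        to = {"A": "G", "C": "T"}[ref]
        base_on_plus = to if not flip else {"A": "T", "C": "G",
                                            "G": "C", "T": "A"}[to]
        mask = rng.random(n_reads) < rate
        matrix[mask, g] = ord(base_on_plus)
        edit_counts[p] = int(mask.sum())

    if error_rate > 0:
        err = rng.random(matrix.shape) < error_rate
        err[:, list(edited_cols)] = False  # errors only at non-programmed
        n_err = int(err.sum())
        if n_err:
            # substitute a uniformly random *different* base
            shift = rng.integers(1, 4, size=n_err)
            lut = {ord(b): i for i, b in enumerate("ACGT")}
            flat = matrix[err]
            idx = np.vectorize(lut.get)(flat)
            matrix[err] = _BASES[(idx + shift) % 4]

    qual = chr(quality + 33) * n_pos
    reads = [(matrix[i].tobytes().decode("ascii"), qual)
             for i in range(n_reads)]

    # Independent verification: recount edits column-wise.
    for p, count in edit_counts.items():
        g = spec.amplicon_index(p)
        ref = spec.protospacer[p - 1]
        to = {"A": "G", "C": "T"}[ref]
        base_on_plus = to if not flip else {"A": "T", "C": "G",
                                            "G": "C", "T": "A"}[to]
        actual = int((matrix[:, g] == ord(base_on_plus)).sum())
        if actual != count:
            raise GenerationError("edit count verification failed")

    if fastq_path is not None:
        with open(fastq_path, "w") as fh:
            for i, (s, q) in enumerate(reads):
                fh.write(f"@read{i}\n{s}\n+\n{q}\n")

    truth = GroundTruth(
        kind="amplicon_reads", seed=seed,
        params={"n_reads": n_reads, "error_rate": error_rate,
                "quality": quality,
                "rates": {str(p): r
                          for p, r in per_position_rates.items()}},
        planted=[{"position": p, "rate": per_position_rates[p],
                  "edited_reads": edit_counts[p],
                  "empirical_rate": edit_counts[p] / n_reads}
                 for p in sorted(per_position_rates)],
    )
    return reads, truth


def simulate_trace_table(seed: int, spec: AmpliconSpec,
                         per_position_rates: dict[int, float],
                         baseline: float = 1000.0):
    """Per-position four-channel peak intensities with programmed edit
    shares at the given protospacer positions (exact, noise-free)."""
    import pandas as pd

    amp = spec.reference
    inten = np.zeros((len(amp), 4))
    chan = {"A": 0, "C": 1, "G": 2, "T": 3}
    for i, b in enumerate(amp):
        inten[i, chan[b]] = baseline
    flip = spec.strand == "-"
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for p, rate in per_position_rates.items():
        ref = spec.protospacer[p - 1]
        to = {"A": "G", "C": "T"}[ref]
        g = spec.amplicon_index(p)
        ref_amp = comp[ref] if flip else ref
        to_amp = comp[to] if flip else to
        inten[g, chan[ref_amp]] = baseline * (1.0 - rate)
        inten[g, chan[to_amp]] = baseline * rate
    df = pd.DataFrame(inten, columns=["A", "C", "G", "T"])
    df.insert(0, "pos", np.arange(1, len(amp) + 1))
    truth = GroundTruth(
        kind="trace_table", seed=seed,
        params={"baseline": baseline},
        planted=[{"position": p, "rate": r}
                 for p, r in sorted(per_position_rates.items())],
    )
    return df, truth


_RULE_VIOLATIONS = ("strand_bias", "low_qd", "low_depth", "cluster",
                    "control_snp")


def simulate_rna_vcfs(seed: int, n_samples: int = 3,
                      shared_true_events: int = 22,
                      private_event_range: tuple[int, int] = (12, 163),
                      decoys_per_rule: int = 1,
                      control_snps: int = 30,
                      out_dir=None,
                      chrom: str = "1",
                      include_boundary_event: bool = True
                      ) -> tuple[dict[str, list], list, GroundTruth]:
    """Treated/control VCF record sets with planted A-to-I edits.

    Shared events appear in every treated sample and pass every filter;
    each decoy violates exactly one named rule; the control sample
    carries the SNP background that control subtraction must remove.
    When ``include_boundary_event`` is set, one shared event sits
    exactly at the filter thresholds (FS=30.0, QD=2.0, DP=30), which
    the strict comparisons must keep.

    Returns (treated record dict, control records, truth); with
    ``out_dir`` the sets are also written as plain VCF files.
    """
    from .rna_offtarget import RnaVariantRecord

    rng = np.random.default_rng(seed)
    pos_cursor = 1000

    def next_pos(gap: int = 500) -> int:
        nonlocal pos_cursor
        pos_cursor += gap + int(rng.integers(0, 100))
        return pos_cursor

    def atoi_alleles():
        return ("A", "G") if rng.random() < 0.5 else ("T", "C")

    def passing_annotations(boundary: bool = False):
        if boundary:
            return 30.0, 2.0, 30
        fs = float(np.round(rng.uniform(0.0, 10.0), 3))
        qd = float(np.round(rng.uniform(5.0, 30.0), 3))
        dp = int(rng.integers(40, 200))
        return fs, qd, dp

    shared = []
    for i in range(shared_true_events):
        ref, alt = atoi_alleles()
        shared.append({"pos": next_pos(), "ref": ref, "alt": alt,
                       "boundary": include_boundary_event and i == 0})

    snps = []
    for _ in range(control_snps):
        ref = "ACGT"[int(rng.integers(4))]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        snps.append({"pos": next_pos(), "ref": ref, "alt": str(alt)})

    treated: dict[str, list] = {}
    truth_decoys = {}
    n_private = {}
    for s in range(n_samples):
        sample = f"treated{s + 1}"
        records = []

        def add(pos, ref, alt, fs, qd, dp):
            alt_reads = max(1, int(dp * rng.uniform(0.05, 0.6)))
            records.append(RnaVariantRecord(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                fisher_strand=fs, qual_by_depth=qd, depth=dp,
                allele_depths=(dp - alt_reads, alt_reads),
                sample_id=sample,
            ))

        for ev in shared:
            fs, qd, dp = passing_annotations(ev["boundary"])
            add(ev["pos"], ev["ref"], ev["alt"], fs, qd, dp)
        lo, hi = private_event_range
        k = int(rng.integers(lo, hi + 1))
        n_private[sample] = k
        for _ in range(k):
            ref, alt = atoi_alleles()
            fs, qd, dp = passing_annotations()
            add(next_pos(), ref, alt, fs, qd, dp)
        for ev in snps:
            fs, qd, dp = passing_annotations()
            add(ev["pos"], ev["ref"], ev["alt"], fs, qd, dp)
        decoys = []
        for _ in range(decoys_per_rule):
            for rule in _RULE_VIOLATIONS:
                ref, alt = atoi_alleles()
                fs, qd, dp = passing_annotations()
                if rule == "strand_bias":
                    fs = float(np.round(rng.uniform(30.01, 80.0), 3))
                    pos = next_pos()
                    add(pos, ref, alt, fs, qd, dp)
                    decoys.append({"rule": rule, "pos": pos,
                                   "ref": ref, "alt": alt})
                elif rule == "low_qd":
                    qd = float(np.round(rng.uniform(0.0, 1.99), 3))
                    pos = next_pos()
                    add(pos, ref, alt, fs, qd, dp)
                    decoys.append({"rule": rule, "pos": pos,
                                   "ref": ref, "alt": alt})
                elif rule == "low_depth":
                    dp = int(rng.integers(1, 30))
                    pos = next_pos()
                    add(pos, ref, alt, fs, qd, dp)
                    decoys.append({"rule": rule, "pos": pos,
                                   "ref": ref, "alt": alt})
                elif rule == "cluster":
                    base = next_pos()
                    members = [base + off for off in (0, 8, 16, 25, 34)]
                    for pos in members:
                        r2, a2 = atoi_alleles()
                        fs, qd, dp = passing_annotations()
                        add(pos, r2, a2, fs, qd, dp)
                        decoys.append({"rule": rule, "pos": pos,
                                       "ref": r2, "alt": a2})
                elif rule == "control_snp":
                    # already planted via the shared SNP background
                    pass
        truth_decoys[sample] = decoys
        records.sort(key=lambda r: (r.chrom, r.pos))
        treated[sample] = records

    control = []
    for ev in snps:
        fs, qd, dp = passing_annotations()
        alt_reads = max(1, int(dp * rng.uniform(0.3, 0.6)))
        control.append(RnaVariantRecord(
            chrom=chrom, pos=ev["pos"], ref=ev["ref"], alt=ev["alt"],
            fisher_strand=fs, qual_by_depth=qd, depth=dp,
            allele_depths=(dp - alt_reads, alt_reads),
            sample_id="control",
        ))

    truth = GroundTruth(
        kind="rna_vcfs", seed=seed,
        params={"n_samples": n_samples,
                "shared_true_events": shared_true_events,
                "private_event_range": list(private_event_range),
                "decoys_per_rule": decoys_per_rule,
                "control_snps": control_snps,
                "n_private": n_private},
        planted=[{"role": "shared_event", **ev} for ev in shared]
        + [{"role": "control_snp", **ev} for ev in snps]
        + [{"role": "decoy", "sample": s, **d}
           for s, ds in truth_decoys.items() for d in ds],
    )

    if out_dir is not None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sample, records in treated.items():
            write_rna_vcf(records, out / f"{sample}.vcf", sample, chrom)
        write_rna_vcf(control, out / "control.vcf", "control", chrom)

    return treated, control, truth


def write_rna_vcf(records, path, sample_name: str, chrom: str,
                  contig_length: int = 200_000_000) -> None:
    """Write records as a minimal well-formed VCF 4.2 file."""
    header = (
        "##fileformat=VCFv4.2\n"
        f"##contig=<ID={chrom},length={contig_length}>\n"
        '##INFO=<ID=FS,Number=1,Type=Float,Description="FisherStrand">\n'
        '##INFO=<ID=QD,Number=1,Type=Float,Description="QualByDepth">\n'
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,'
        'Description="Allelic depths">\n'
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
        f"\t{sample_name}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            ad = f"{r.allele_depths[0]},{r.allele_depths[1]}"
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t100\t.\t"
                f"FS={r.fisher_strand};QD={r.qual_by_depth};DP={r.depth}"
                f"\tAD\t{ad}\n"
            )
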