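"""End-to-end wiring of the packaged worked examples.

Each check composes the module-level examples: the mdx4cv guide design,
the bystander inventories, a planted off-target search, a
quantification parameter-recovery run and the RNA-filter recovery run.
All inputs are built in memory from packaged fixtures and seeded
generators; nothing is downloaded.
"""

from __future__ import annotations

from . import fixtures, synthetic_data
from .amplicon_quant import quantify_reads
from .design_scan import find_guides_for_variant, get_profile
from .offtarget_search import mismatch_histogram, search
from .rna_offtarget import run_pipeline


def check_mdx4cv_design() -> dict:
    fx = fixtures.build_mdx4cv_fixture()
    ng = find_guides_for_variant(fx.genome, fx.variant, get_profile("NG"))
    ngg = find_guides_for_variant(fx.genome, fx.variant, get_profile("NGG"))
    best = [d for d in ng if d.in_window]
    ok = (len(best) >= 1
          and any(d.target_position == 4 and d.pam_observed == "TGT"
                  and d.strand == "-"
                  and d.protospacer == fixtures.MDX4CV_PROTOSPACER
                  for d in best)
          and not any(d.in_window for d in ngg))
    return {"passed": ok,
            "target_position": best[0].target_position if best else None,
            "pam": best[0].pam_observed if best else None,
            "ngg_in_window_designs": sum(d.in_window for d in ngg)}


def check_bystanders() -> dict:
    fx = fixtures.build_mdx4cv_fixture()
    designs = find_guides_for_variant(fx.genome, fx.variant,
                                      get_profile("NG"))
    d = next(d for d in designs if d.in_window)
    mdx_ok = (d.bystander_adenines_in_window == []
              and d.window_cytosines == [6, 8])
    spec = fixtures.dysf_like_amplicon_spec()
    proto = spec.protospacer
    window = spec.editor.window
    adenines = [p for p, b in enumerate(proto, 1) if b == "A"]
    dysf_ok = adenines == [6, 8, 11]
    return {"passed": mdx_ok and dysf_ok,
            "mdx4cv_window_cytosines": d.window_cytosines,
            "dysf_like_adenines": adenines,
            "window": list(window)}


def check_offtarget_search(seed: int = 101) -> dict:
    genome = synthetic_data.gen_genome(seed, 100_000)
    spec = {1: 1, 2: 2, 3: 55}
    planted, truth = synthetic_data.plant_offtargets(
        genome, fixtures.MDX4CV_PROTOSPACER, "NGN", spec, seed)
    sites = search(planted, fixtures.MDX4CV_PROTOSPACER,
                   pam_pattern="NGN", max_mismatch=3)
    hist = mismatch_histogram(sites)
    ok = hist == spec
    return {"passed": ok, "histogram": {str(k): v for k, v in hist.items()}}


def check_quantification(seed: int = 202, n_reads: int = 20_000) -> dict:
    spec = fixtures.mdx4cv_amplicon_spec()
    rate = 0.326
    reads, truth = synthetic_data.simulate_amplicon_reads(
        seed, spec, n_reads, {4: rate}, error_rate=0.001)
    table, alleles = quantify_reads(reads, spec)
    measured = table.frequency(4)
    se = (rate * (1 - rate) / n_reads) ** 0.5
    ok = abs(measured - rate) <= 3 * se
    return {"passed": ok, "programmed": rate,
            "measured": round(measured, 4), "n_reads": n_reads}


def check_rna_filter(seed: int = 303) -> dict:
    treated, control, truth = synthetic_data.simulate_rna_vcfs(
        seed, n_samples=3, shared_true_events=22, decoys_per_rule=1)
    report = run_pipeline(treated, control)
    planted = {("1", ev["pos"], ev["ref"], ev["alt"])
               for ev in truth.planted if ev["role"] == "shared_event"}
    ok = report["shared_by_all"] == planted \
        and len(report["shared_by_all"]) == 22
    return {"passed": ok,
            "n_shared_by_all": len(report["shared_by_all"]),
            "expected": 22}


def run_all_checks() -> dict:
    checks = {
        "mdx4cv_design": check_mdx4cv_design(),
        "bystander_inventory": check_bystanders(),
        "offtarget_search": check_offtarget_search(),
        "quantification_recovery": check_quantification(),
        "rna_filter_recovery": check_rna_filter(),
    }
    return {"checks": checks,
            "all_passed": all(c["passed"] for c in checks.values())}
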