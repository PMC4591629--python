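"""Independent brute-force reference for the allelic workflow.

Deliberately written with plain Python loops and no calls into the
package, so it can serve as an oracle for the vectorized implementation.
A site is a dict with keys ctrl_a, ctrl_b, exp_a, exp_b.
"""

MIN_READS = {"rna": 4, "chip": 5}


def brute_force_region(sites, mode="rna", low=0.3, high=0.7,
                       deviation=0.15, fold=2.0):
    """Run filter -> phase -> (chip depth filter) -> aggregate -> gate -> percent.

    Returns a dict with the retained original site indices, pooled ratios,
    pooled allelic read totals, percent silencing and the gate outcome.
    """
    # stage 0: drop zero-total sites
    usable = []
    for i, s in enumerate(sites):
        if s["ctrl_a"] + s["ctrl_b"] > 0 and s["exp_a"] + s["exp_b"] > 0:
            usable.append((i, s))
    # stage 1: biallelic control ratio in [low, high]
    biallelic = []
    for i, s in usable:
        r = s["ctrl_a"] / (s["ctrl_a"] + s["ctrl_b"])
        if low <= r <= high:
            biallelic.append((i, s))
    # stage 2: phase: allele with fewer experimental reads (tie -> a)
    phased = []
    for i, s in biallelic:
        which = "a" if s["exp_a"] <= s["exp_b"] else "b"
        sil_c = s["ctrl_a"] if which == "a" else s["ctrl_b"]
        sil_e = s["exp_a"] if which == "a" else s["exp_b"]
        phased.append((i, sil_c, s["ctrl_a"] + s["ctrl_b"],
                       sil_e, s["exp_a"] + s["exp_b"]))
    if not phased:
        return {"retained": [], "n_initial": 0}
    # stage 3 (chip): single pass against original per-condition mean totals
    if mode == "chip":
        mean_c = sum(p[2] for p in phased) / len(phased)
        mean_e = sum(p[4] for p in phased) / len(phased)
        phased = [p for p in phased
                  if mean_c / fold <= p[2] <= mean_c * fold
                  and mean_e / fold <= p[4] <= mean_e * fold]
        if not phased:
            return {"retained": [], "n_initial": 0}
    n_initial = len(phased)
    # stage 4: pool, remove deviating sites once, re-pool
    r_c = sum(p[1] for p in phased) / sum(p[2] for p in phased)
    r_e = sum(p[3] for p in phased) / sum(p[4] for p in phased)
    kept = [p for p in phased
            if abs(p[1] / p[2] - r_c) <= deviation
            and abs(p[3] / p[4] - r_e) <= deviation]
    if not kept:
        return {"retained": [], "n_initial": n_initial,
                "all_removed": True}
    r_c = sum(p[1] for p in kept) / sum(p[2] for p in kept)
    r_e = sum(p[3] for p in kept) / sum(p[4] for p in kept)
    reads_c = sum(p[2] for p in kept)
    reads_e = sum(p[4] for p in kept)
    gate = reads_c >= MIN_READS[mode] and reads_e >= MIN_READS[mode]
    percent = 100.0 * (r_c - r_e) / r_c if r_c > 0 else None
    return {"retained": sorted(p[0] for p in kept), "n_initial": n_initial,
            "ctrl_ratio": r_c, "exp_ratio": r_e,
            "reads_ctrl": reads_c, "reads_exp": reads_e,
            "gate": gate, "percent": percent}
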