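"""EHH, integrated haplotype homozygosity (iHH) and the cross-population
XP-EHH statistic.

EHH at a (core, target) pair is the probability that two haplotypes drawn
without replacement from the population are identical over the inclusive
site span between core and target. Note the convention used here: EHH at
zero distance is the core-site homozygosity (the core site itself is part
of the span), so EHH is a pure function of the span.

iHH integrates a population's EHH against physical position away from the
core, in both directions, truncated where the EHH of the two populations
POOLED first drops below a cutoff (common span for both populations), at a
data edge, or at an inter-site gap larger than ``max_gap`` (both flagged).

XP-EHH at a SNP is ln(iHH_focal / iHH_ref); raw scores are standardized to
zero mean and unit variance over all scored SNPs in the run. Positive
standardized scores indicate unusually extended haplotypes in the focal
population, the signature of a recent sweep there.
"""

from __future__ import annotations

import numpy as np

from .datatypes import HaplotypeMatrix, SnpScore

DEFAULT_CUTOFF = 0.05
DEFAULT_MAX_GAP = 200_000


def _pair_fraction(counts: np.ndarray, n: int) -> float:
    """Probability two draws without replacement fall in the same group."""
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def ehh(hm: HaplotypeMatrix, core: int, target: int) -> float:
    """EHH over the inclusive span [min(core,target), max(core,target)].

    Haplotypes are grouped by identity over the span; EHH is the fraction
    of haplotype pairs falling in the same group.
    """
    n = hm.n_haplotypes
    if n < 2:
        raise ValueError("EHH undefined for fewer than 2 haplotypes")
    lo, hi = min(core, target), max(core, target)
    if lo < 0 or hi >= hm.n_sites:
        raise ValueError("core/target site index out of range")
    span = hm.alleles[:, lo : hi + 1]
    _, counts = np.unique(span, axis=0, return_counts=True)
    return _pair_fraction(counts, n)


def _extend(
    alleles: np.ndarray,
    positions: np.ndarray,
    pop_rows: np.ndarray | None,
    core: int,
    cutoff: float,
    max_gap: int,
    direction: int,
):
    """Walk site-by-site from the core in one direction.

    Returns (ehh_values, pos_values, edge_flag) for the retained span,
    starting at the core. Truncation tests use the pooled haplotype set;
    the returned EHH curve is for ``pop_rows`` (or pooled when None).
    """
    n_hap, n_sites = alleles.shape
    n_pop = n_hap if pop_rows is None else pop_rows.size

    g = alleles[:, core].astype(np.int64)
    counts = np.bincount(g)
    if pop_rows is None:
        pop_e = _pair_fraction(counts, n_hap)
    else:
        pop_e = _pair_fraction(np.bincount(g[pop_rows]), n_pop)
    pooled_e = _pair_fraction(counts, n_hap)
    if pooled_e < cutoff:
        return [pop_e], [int(positions[core])], False, False

    ehh_vals = [pop_e]
    pos_vals = [int(positions[core])]
    edge = False
    j = core
    n_groups = int(g.max()) + 1
    while True:
        jn = j + direction
        if jn < 0 or jn >= n_sites:
            edge = True
            break
        if abs(int(positions[jn]) - int(positions[j])) > max_gap:
            edge = True
            break
        col = alleles[:, jn]
        g = g * 2 + col
        g, counts = _relabel(g)
        n_groups = counts.size
        pooled_e = _pair_fraction(counts, n_hap)
        if pooled_e < cutoff:
            break
        if pop_rows is None:
            ehh_vals.append(pooled_e)
        else:
            ehh_vals.append(_pair_fraction(np.bincount(g[pop_rows]), n_pop))
        pos_vals.append(int(positions[jn]))
        j = jn
        if n_groups == n_hap:  # all singletons: EHH is 0 from here on
            break
    return ehh_vals, pos_vals, edge, True


def _relabel(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Compact group ids to 0..k-1 and return group sizes."""
    uniq, inv, counts = np.unique(g, return_inverse=True, return_counts=True)
    return inv, counts


def _integrate(ehh_vals: list[float], pos_vals: list[int]) -> float:
    if len(ehh_vals) < 2:
        return 0.0
    x = np.abs(np.asarray(pos_vals, dtype=float) - pos_vals[0])
    return float(np.trapezoid(np.asarray(ehh_vals), x))


def ihh(
    hm_pop: HaplotypeMatrix,
    hm_pooled: HaplotypeMatrix,
    core: int,
    cutoff: float = DEFAULT_CUTOFF,
    max_gap: int = DEFAULT_MAX_GAP,
) -> tuple[float, bool]:
    """Integrated haplotype homozygosity of one population at a core site.

    ``hm_pop`` holds the population's haplotypes, ``hm_pooled`` both
    populations on the same site set (used only to decide the truncation
    span). Returns (iHH in bp, edge_flag).
    """
    if not np.array_equal(hm_pop.positions, hm_pooled.positions):
        raise ValueError("hm_pop and hm_pooled must share the same site set")
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie in (0,1)")
    total = 0.0
    edge = False
    for direction in (-1, 1):
        ep, pp, e, ok = _extend(
            hm_pooled.alleles, hm_pooled.positions, None, core, cutoff, max_gap, direction
        )
        if not ok:  # pooled EHH below cutoff at the core itself
            return 0.0, False
        evals, pvals, e2, _ = _extend_follow(
            hm_pop.alleles, hm_pop.positions, core, len(pp), direction
        )
        total += _integrate(evals, pvals)
        edge = edge or e
    return total, edge


def _extend_follow(alleles, positions, core, span_len, direction):
    """Population EHH curve over a pre-decided span of ``span_len`` sites."""
    n_hap = alleles.shape[0]
    g = alleles[:, core].astype(np.int64)
    counts = np.bincount(g)
    ehh_vals = [_pair_fraction(counts, n_hap)]
    pos_vals = [int(positions[core])]
    j = core
    for _ in range(span_len - 1):
        jn = j + direction
        g = g * 2 + alleles[:, jn]
        g, counts = _relabel(g)
        ehh_vals.append(_pair_fraction(counts, n_hap))
        pos_vals.append(int(positions[jn]))
        j = jn
    return ehh_vals, pos_vals, False, True


def _scan_one_core(alleles, positions, is_focal, core, cutoff, max_gap):
    """iHH for both populations at one core, sharing the pooled span.

    Because haplotype identity over a span does not depend on population
    labels, the pooled grouping restricted to a population's rows equals
    that population's own grouping, so one grouping pass serves all three
    EHH curves. Haplotypes that fall into singleton groups can never again
    contribute identical pairs and are dropped from the working set, which
    keeps each extension step linear in the number of still-grouped rows.
    """
    n_hap = alleles.shape[0]
    n_f = int(is_focal.sum())
    n_r = n_hap - n_f
    denom_pool = n_hap * (n_hap - 1)
    denom_f = n_f * (n_f - 1)
    denom_r = n_r * (n_r - 1)

    col0 = alleles[:, core]
    c1 = int(col0.sum())
    c0 = n_hap - c1
    pooled0 = (c0 * (c0 - 1) + c1 * (c1 - 1)) / denom_pool
    f1 = int(col0[is_focal].sum())
    f0 = n_f - f1
    r1 = c1 - f1
    r0 = c0 - f0
    ehh_f0 = (f0 * (f0 - 1) + f1 * (f1 - 1)) / denom_f
    ehh_r0 = (r0 * (r0 - 1) + r1 * (r1 - 1)) / denom_r
    if pooled0 < cutoff:
        return 0.0, 0.0, False

    ihh_f = 0.0
    ihh_r = 0.0
    edge = False
    n_sites = alleles.shape[1]

    for direction in (-1, 1):
        active = np.arange(n_hap)
        g = col0.astype(np.int64)
        focal_mask = is_focal.copy()
        ef = [ehh_f0]
        er = [ehh_r0]
        pv = [int(positions[core])]
        j = core
        while True:
            jn = j + direction
            if jn < 0 or jn >= n_sites:
                edge = True
                break
            if abs(int(positions[jn]) - int(positions[j])) > max_gap:
                edge = True
                break
            key = g * 2 + alleles[active, jn]
            counts = np.bincount(key)
            nz = np.flatnonzero(counts)
            relabel = np.empty(counts.size, dtype=np.int64)
            relabel[nz] = np.arange(nz.size)
            g = relabel[key]
            counts = counts[nz]
            pooled = float((counts * (counts - 1)).sum()) / denom_pool
            if pooled < cutoff:
                break
            fc = np.bincount(g[focal_mask], minlength=counts.size)
            rc = counts - fc
            ef.append(float((fc * (fc - 1)).sum()) / denom_f)
            er.append(float((rc * (rc - 1)).sum()) / denom_r)
            pv.append(int(positions[jn]))
            j = jn
            if counts.size == active.size:  # all singletons: EHH stays 0
                break
            keep = counts[g] > 1
            if not keep.all():
                active = active[keep]
                g = _relabel(g[keep])[0]
                focal_mask = focal_mask[keep]
        ihh_f += _integrate(ef, pv)
        ihh_r += _integrate(er, pv)
    return ihh_f, ihh_r, edge


def _make_scan_kernel():
    """Compile the per-chromosome scan with numba when available.

    The jitted kernel runs the same algorithm as _scan_one_core for every
    core site; returns None when numba is not installed (the numpy path is
    used instead).
    """
    try:
        import numba
    except ImportError:
        return None

    @numba.njit(cache=False)
    def kernel(alleles, positions, is_focal, cutoff, max_gap):  # pragma: no cover
        n_hap, n_sites = alleles.shape
        n_f = 0
        for i in range(n_hap):
            if is_focal[i]:
                n_f += 1
        n_r = n_hap - n_f
        denom_pool = n_hap * (n_hap - 1)
        denom_f = n_f * (n_f - 1)
        denom_r = n_r * (n_r - 1)

        out_f = np.zeros(n_sites)
        out_r = np.zeros(n_sites)
        out_edge = np.zeros(n_sites, dtype=np.uint8)

        g = np.empty(n_hap, dtype=np.int64)
        label = np.full(4 * n_hap + 2, -1, dtype=np.int64)
        cnt = np.zeros(n_hap + 1, dtype=np.int64)
        fcnt = np.zeros(n_hap + 1, dtype=np.int64)

        for core in range(n_sites):
            c1 = 0
            f1 = 0
            for i in range(n_hap):
                if alleles[i, core] == 1:
                    c1 += 1
                    if is_focal[i]:
                        f1 += 1
            c0 = n_hap - c1
            f0 = n_f - f1
            r1 = c1 - f1
            r0 = c0 - f0
            pooled0 = (c0 * (c0 - 1) + c1 * (c1 - 1)) / denom_pool
            if pooled0 < cutoff:
                continue
            ef0 = (f0 * (f0 - 1) + f1 * (f1 - 1)) / denom_f
            er0 = (r0 * (r0 - 1) + r1 * (r1 - 1)) / denom_r

            for direction in (-1, 1):
                for i in range(n_hap):
                    g[i] = alleles[i, core]
                ngroups = 2
                prev_ef = ef0
                prev_er = er0
                prev_pos = positions[core]
                j = core
                while True:
                    jn = j + direction
                    if jn < 0 or jn >= n_sites:
                        out_edge[core] = 1
                        break
                    gap = positions[jn] - positions[j]
                    if gap < 0:
                        gap = -gap
                    if gap > max_gap:
                        out_edge[core] = 1
                        break
                    # relabel groups extended by the next column
                    ng = 0
                    for i in range(n_hap):
                        k = g[i] * 2 + alleles[i, jn]
                        if label[k] == -1:
                            label[k] = ng
                            ng += 1
                        g[i] = label[k]
                    for i in range(n_hap):  # reset used label slots
                        k2 = g[i]
                        cnt[k2] = 0
                        fcnt[k2] = 0
                    for k in range(2 * ngroups):
                        label[k] = -1
                    ngroups = ng
                    for i in range(n_hap):
                        cnt[g[i]] += 1
                        if is_focal[i]:
                            fcnt[g[i]] += 1
                    pooled_pairs = 0
                    f_pairs = 0
                    r_pairs = 0
                    for k in range(ng):
                        c = cnt[k]
                        fc = fcnt[k]
                        rc = c - fc
                        pooled_pairs += c * (c - 1)
                        f_pairs += fc * (fc - 1)
                        r_pairs += rc * (rc - 1)
                    pooled = pooled_pairs / denom_pool
                    if pooled < cutoff:
                        break
                    ef = f_pairs / denom_f
                    er = r_pairs / denom_r
                    dist = positions[jn] - positions[j]
                    if dist < 0:
                        dist = -dist
                    out_f[core] += 0.5 * (ef + prev_ef) * dist
                    out_r[core] += 0.5 * (er + prev_er) * dist
                    prev_ef = ef
                    prev_er = er
                    j = jn
        return out_f, out_r, out_edge

    return kernel


_SCAN_KERNEL = None
_SCAN_KERNEL_TRIED = False


def _get_kernel():
    global _SCAN_KERNEL, _SCAN_KERNEL_TRIED
    if not _SCAN_KERNEL_TRIED:
        _SCAN_KERNEL = _make_scan_kernel()
        _SCAN_KERNEL_TRIED = True
    return _SCAN_KERNEL


def xpehh_scan(
    hm: HaplotypeMatrix | list[HaplotypeMatrix],
    focal: str = "focal",
    cutoff: float = DEFAULT_CUTOFF,
    max_gap: int = DEFAULT_MAX_GAP,
    standardize: bool = True,
    use_kernel: bool = True,
) -> list[SnpScore]:
    """Score every SNP with XP-EHH; standardize across the whole run.

    Accepts one HaplotypeMatrix or a list (one per chromosome); raw scores
    ln(iHH_focal/iHH_ref) are standardized jointly over all chromosomes.
    Sites where either iHH is 0 carry an undefined raw score and are
    excluded from standardization.
    """
    mats = [hm] if isinstance(hm, HaplotypeMatrix) else list(hm)
    scores: list[SnpScore] = []
    for m in mats:
        pops = m.populations()
        if len(pops) != 2:
            raise ValueError(f"need exactly 2 population labels, got {pops}")
        if focal not in pops:
            raise ValueError(f"focal label {focal!r} not among {pops}")
        is_focal = m.hap_pop == focal
        if not 0 < cutoff < 1:
            raise ValueError("cutoff must lie in (0,1)")
        kernel = _get_kernel() if use_kernel else None
        if kernel is not None and m.n_sites:
            fv, rv, ev = kernel(
                np.ascontiguousarray(m.alleles),
                m.positions.astype(np.int64),
                is_focal,
                float(cutoff),
                int(max_gap),
            )
            results = zip(fv, rv, ev.astype(bool))
        else:
            results = (
                _scan_one_core(m.alleles, m.positions, is_focal, core, cutoff, max_gap)
                for core in range(m.n_sites)
            )
        for core, (f, r, edge) in enumerate(results):
            f, r = float(f), float(r)
            raw = float(np.log(f / r)) if (f > 0 and r > 0) else None
            scores.append(
                SnpScore(
                    chrom=m.chrom,
                    pos=int(m.positions[core]),
                    ihh_focal=f,
                    ihh_ref=r,
                    xpehh_raw=raw,
                    edge_flag=bool(edge),
                )
            )
    if standardize:
        standardize_scores(scores)
    return scores


def standardize_scores(scores: list[SnpScore]) -> None:
    """Z-standardize defined raw scores in place (genome-wide moments)."""
    raw = np.array([s.xpehh_raw for s in scores if s.xpehh_raw is not None])
    if raw.size < 2:
        raise ValueError("fewer than 2 defined raw scores; cannot standardize")
    mu = raw.mean()
    sd = raw.std(ddof=0)
    if sd == 0:
        raise ValueError("raw scores are constant; cannot standardize")
    for s in scores:
        if s.xpehh_raw is not None:
            s.xpehh_z = (s.xpehh_raw - mu) / sd
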