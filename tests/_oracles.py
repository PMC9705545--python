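"""Independent brute-force reference implementations used only by tests.

These re-derive every score from the written rules with plain Python
loops, deliberately sharing no code with the package.
"""

from __future__ import annotations


def trap(x: float, a: float, b: float, c: float, d: float) -> float:
    if x <= a or x >= d:
        return 0.0
    if b <= x <= c:
        return 100.0
    if x < b:
        return 100.0 * (x - a) / (b - a)
    return 100.0 * (d - x) / (d - c)


def oracle_cell_score(tmin, tmax, prec, p, combiner: str = "product") -> float:
    """Best combined season score for one cell, enumerating all 12 starts."""
    best = 0.0
    for start in range(12):
        months = [(start + k) % 12 for k in range(p.g_used)]
        if any(tmin[m] < p.ktmp for m in months):
            continue
        s_tmin = min(
            trap(tmin[m], p.t_min, p.t_opmin, p.t_opmax, p.t_max) for m in months
        )
        s_tmax = min(
            trap(tmax[m], p.t_min, p.t_opmin, p.t_opmax, p.t_max) for m in months
        )
        total = 0.0
        for m in months:
            total = total + prec[m]
        s_rain = trap(total, p.r_min, p.r_opmin, p.r_opmax, p.r_max)
        if combiner == "product":
            a = s_tmin * s_rain / 100.0
            b = s_tmax * s_rain / 100.0
        else:
            a = min(s_tmin, s_rain)
            b = min(s_tmax, s_rain)
        if a == 0.0 and b == 0.0:
            combined = 0.0
        elif b == 0.0:
            combined = a
        elif a == 0.0:
            combined = b
        else:
            combined = (a * a + b * b) / (a + b)
        if combined > best:
            best = combined
    return best


def oracle_area_fraction(scores, region, areas, threshold, nodata=-9999.0) -> float:
    """Loop-based latitude-weighted suitable-area percent of one region."""
    num = 0.0
    den = 0.0
    n_rows = len(scores)
    for r in range(n_rows):
        for c in range(len(scores[0])):
            if not region[r][c] or scores[r][c] == nodata:
                continue
            den += areas[r]
            if scores[r][c] >= threshold:
                num += areas[r]
    return 100.0 * num / den
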