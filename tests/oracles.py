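"""Independent brute-force oracles for the texture, agreement and ROC code.

Everything here is written as naive explicit loops over voxels, pairs,
lines and zones — deliberately sharing no code with the package — so
the vectorized implementations can be checked against exhaustive
enumeration on small ROIs.
"""

from __future__ import annotations

import numpy as np

# 13 unique direction offsets, one per +/- pair (lexicographically positive)
OFFSETS_13 = [
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) > (0, 0, 0)
]
OFFSETS_26 = [
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) != (0, 0, 0)
]


def glcm_matrix_oracle(levels, mask, off):
    """Symmetric normalized co-occurrence matrix by explicit pair loops."""
    ng = int(levels[mask].max())
    counts = np.zeros((ng, ng))
    nr, nc, nz = levels.shape
    for r in range(nr):
        for c in range(nc):
            for z in range(nz):
                if not mask[r, c, z]:
                    continue
                r2, c2, z2 = r + off[0], c + off[1], z + off[2]
                if 0 <= r2 < nr and 0 <= c2 < nc and 0 <= z2 < nz and mask[r2, c2, z2]:
                    counts[levels[r, c, z] - 1, levels[r2, c2, z2] - 1] += 1
    counts = counts + counts.T
    total = counts.sum()
    return counts / total if total else counts


def glrlm_matrix_oracle(levels, mask, off):
    """Run-length counts by walking every line voxel by voxel."""
    nr, nc, nz = levels.shape
    ng = int(levels[mask].max())
    runs = []
    # line starts: voxels whose predecessor along -off is outside the grid
    for r in range(nr):
        for c in range(nc):
            for z in range(nz):
                pr, pc, pz = r - off[0], c - off[1], z - off[2]
                if 0 <= pr < nr and 0 <= pc < nc and 0 <= pz < nz:
                    continue
                # walk the line
                cur_level, cur_len = None, 0
                rr, cc, zz = r, c, z
                while 0 <= rr < nr and 0 <= cc < nc and 0 <= zz < nz:
                    lvl = levels[rr, cc, zz] if mask[rr, cc, zz] else None
                    if lvl == cur_level and lvl is not None:
                        cur_len += 1
                    else:
                        if cur_level is not None:
                            runs.append((cur_level, cur_len))
                        cur_level, cur_len = lvl, 1
                    rr, cc, zz = rr + off[0], cc + off[1], zz + off[2]
                if cur_level is not None:
                    runs.append((cur_level, cur_len))
    lmax = max(l for _, l in runs)
    counts = np.zeros((ng, lmax))
    for lvl, length in runs:
        counts[lvl - 1, length - 1] += 1
    return counts


def glszm_matrix_oracle(levels, mask):
    """Size-zone counts via flood fill (26-connectivity)."""
    ng = int(levels[mask].max())
    visited = np.zeros_like(mask, dtype=bool)
    zones = []
    nr, nc, nz = levels.shape
    for r in range(nr):
        for c in range(nc):
            for z in range(nz):
                if not mask[r, c, z] or visited[r, c, z]:
                    continue
                lvl = levels[r, c, z]
                stack, size = [(r, c, z)], 0
                visited[r, c, z] = True
                while stack:
                    cr, cc, cz = stack.pop()
                    size += 1
                    for dr, dc, dz in OFFSETS_26:
                        nrr, ncc, nzz = cr + dr, cc + dc, cz + dz
                        if (
                            0 <= nrr < nr and 0 <= ncc < nc and 0 <= nzz < nz
                            and mask[nrr, ncc, nzz]
                            and not visited[nrr, ncc, nzz]
                            and levels[nrr, ncc, nzz] == lvl
                        ):
                            visited[nrr, ncc, nzz] = True
                            stack.append((nrr, ncc, nzz))
                zones.append((lvl, size))
    smax = max(s for _, s in zones)
    counts = np.zeros((ng, smax))
    for lvl, size in zones:
        counts[lvl - 1, size - 1] += 1
    return counts


def gldm_matrix_oracle(levels, mask, alpha=0):
    """Dependence counts: per voxel, 1 + equal-level 26-neighbors in mask."""
    nr, nc, nz = levels.shape
    ng = int(levels[mask].max())
    entries = []
    for r in range(nr):
        for c in range(nc):
            for z in range(nz):
                if not mask[r, c, z]:
                    continue
                dep = 1
                for dr, dc, dz in OFFSETS_26:
                    rr, cc, zz = r + dr, c + dc, z + dz
                    if (
                        0 <= rr < nr and 0 <= cc < nc and 0 <= zz < nz
                        and mask[rr, cc, zz]
                        and abs(int(levels[rr, cc, zz]) - int(levels[r, c, z])) <= alpha
                    ):
                        dep += 1
                entries.append((levels[r, c, z], dep))
    dmax = max(d for _, d in entries)
    counts = np.zeros((ng, dmax))
    for lvl, dep in entries:
        counts[lvl - 1, dep - 1] += 1
    return counts


def ngtdm_tables_oracle(levels, mask):
    """(n_i, s_i, p_i, nvp) by explicit neighbor averaging."""
    nr, nc, nz = levels.shape
    ng = int(levels[mask].max())
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    nvp = 0
    for r in range(nr):
        for c in range(nc):
            for z in range(nz):
                if not mask[r, c, z]:
                    continue
                nbrs = []
                for dr, dc, dz in OFFSETS_26:
                    rr, cc, zz = r + dr, c + dc, z + dz
                    if 0 <= rr < nr and 0 <= cc < nc and 0 <= zz < nz and mask[rr, cc, zz]:
                        nbrs.append(levels[rr, cc, zz])
                if not nbrs:
                    continue
                nvp += 1
                i = levels[r, c, z]
                n_i[i - 1] += 1
                s_i[i - 1] += abs(i - float(np.mean(nbrs)))
    return n_i, s_i, (n_i / nvp if nvp else n_i), nvp


def auc_pairs_oracle(scores, truth):
    """AUC as the exhaustive case-control pair-comparison probability."""
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def icc21_oracle(r1, r2):
    """ICC(2,1) from the explicitly tabulated two-way ANOVA."""
    data = np.column_stack([np.asarray(r1, float), np.asarray(r2, float)])
    n, k = data.shape
    grand = data.mean()
    ss_rows = k * sum((data[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = n * sum((data[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = ((data - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
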