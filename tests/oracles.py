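"""Independent oracles used by the test suite: implementations that share no
code path with the package."""

import numpy as np


def brute_force_hbond_count(positions, donors, acceptors, criterion):
    """O(n²) double-loop recount of the geometric hydrogen-bond criterion."""
    count = 0
    for d, h in zip(donors.indices, donors.hydrogens):
        for a in acceptors.indices:
            if d == a:
                continue
            da = positions[a] - positions[d]
            dist = np.sqrt(np.dot(da, da))
            dh = positions[h] - positions[d]
            cosang = np.dot(da, dh) / (np.linalg.norm(da) * np.linalg.norm(dh))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if dist <= criterion.distance_cutoff and ang <= criterion.angle_cutoff:
                count += 1
    return count


def quaternion_rmsd(ref, mov):
    """Horn's quaternion method for minimal superposition RMSD."""
    x = ref - ref.mean(axis=0)
    y = mov - mov.mean(axis=0)
    s = y.T @ x
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz]])
    lam = np.linalg.eigvalsh(k)[-1]
    msd = (np.sum(x**2) + np.sum(y**2) - 2.0 * lam) / len(x)
    return np.sqrt(max(msd, 0.0))
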