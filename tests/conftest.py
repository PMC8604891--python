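import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pqmchal.cohort import sample_cohort_profiles
from pqmchal.grids import DoseGrid, StructureMask
from pqmchal.painter import DosePainter
from pqmchal.phantom import build_phantom, default_phantom_spec
from pqmchal.scoring import default_scheme

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_dose(values, spacing=(2.0, 2.0, 2.0)):
    return DoseGrid(values=np.asarray(values, float), spacing_mm=spacing)


def make_mask(voxels, name="s", spacing=(2.0, 2.0, 2.0)):
    return StructureMask(name=name, voxels=np.asarray(voxels, bool), spacing_mm=spacing)


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def phantom():
    spec = default_phantom_spec()
    masks, empty = build_phantom(spec)
    return spec, masks, empty


@pytest.fixture(scope="session")
def painter(phantom, scheme):
    spec, masks, _ = phantom
    return DosePainter(masks, spec.spacing_mm, [m for m, _ in scheme.metrics])


@pytest.fixture(scope="session")
def small_cohort():
    return sample_cohort_profiles(14, seed=42)


# ---------------------------------------------------------------------------
# independent oracles (deliberately brute-force, never share code with the
# implementation they check)


def oracle_dose_at_fraction(doses, fraction):
    """Discrete quantile: dose of the k-th hottest voxel, k = ceil(f*N)."""
    d = np.sort(np.asarray(doses, float))[::-1]
    k = int(np.ceil(fraction * d.size))
    return float(d[k - 1])


def oracle_volume_at_dose(doses, d_gy):
    d = np.asarray(doses, float)
    return 100.0 * float(np.count_nonzero(d >= d_gy)) / d.size


def oracle_cn(doses_flat, target_flat, ref, voxvol):
    d = np.asarray(doses_flat, float)
    t = np.asarray(target_flat, bool)
    covered = d >= ref
    tvri = np.count_nonzero(covered & t) * voxvol
    tv = np.count_nonzero(t) * voxvol
    vri = np.count_nonzero(covered) * voxvol
    if vri == 0:
        return 0.0
    return (tvri / tv) * (tvri / vri)


def oracle_wilcoxon(d):
    """Full 2^n enumeration of sign assignments (ties via average ranks)."""
    import itertools

    from scipy.stats import rankdata

    d = np.asarray(d, float)
    d = d[d != 0]
    r = rankdata(np.abs(d))
    w_obs = r[d > 0].sum()
    ws = np.array(
        [sum(ri for ri, s in zip(r, signs) if s)
         for signs in itertools.product([0, 1], repeat=len(d))]
    )
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return float(w_obs), float(min(1.0, 2 * min(p_le, p_ge)))


def oracle_spearman(x, y):
    """Direct average-rank Pearson formula, written out longhand."""
    def avg_ranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(v.size)
        i = 0
        while i < v.size:
            j = i
            while j + 1 < v.size and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i: j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom)


def oracle_ols(x, y):
    """Normal equations for simple linear regression."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    slope = ((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum()
    return slope, ym - slope * xm
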