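import numpy as np
import pytest

from hic3d.datamodel import ContactMap, ContactModel, MarkovPrior, Structure3D, TrackCovariates, TrackGLM


def make_instance(seed=0, n=5, beta0=1.0, beta1=-1.5, n_cov=3, lam=0.7,
                  gap_weight_mode="linear_gap", loci=None):
    """Small random single-track instance with known coefficients.

    Counts are Poisson draws from the model at the true structure, so the
    instance is self-consistent; availability covers every locus.
    """
    rng = np.random.default_rng(seed)
    if loci is None:
        loci = np.arange(n)
    loci = np.asarray(loci)
    n = loci.size
    coords = np.cumsum(rng.normal(size=(n, 3)), axis=0)
    structure = Structure3D(loci, coords)
    n_bins = int(loci.max()) + 1
    x = np.clip(rng.uniform(size=(n_bins, 3))[:, :n_cov], 1e-9, None)
    covs = TrackCovariates("t", x) if n_cov else None
    beta_cov = rng.uniform(0.2, 0.6, size=n_cov)
    entries = {}
    pos = {int(b): k for k, b in enumerate(loci)}
    for a in range(n):
        for b in range(a + 1, n):
            d = np.linalg.norm(coords[a] - coords[b])
            eta = beta0 + beta1 * np.log(d)
            if n_cov:
                eta += float(np.log(x[loci[a]] * x[loci[b]]) @ beta_cov)
            c = rng.poisson(np.exp(eta))
            if c > 0:
                entries[(int(loci[a]), int(loci[b]))] = int(c)
    avail = np.isin(np.arange(n_bins), loci)
    cmap = ContactMap("t", n_bins, entries, available=avail)
    model = ContactModel(
        tracks={"t": TrackGLM(beta0, beta1, beta_cov)},
        markov=MarkovPrior(lam=lam, gap_weight_mode=gap_weight_mode),
    )
    return cmap, covs, structure, model


@pytest.fixture
def small_instance():
    return make_instance(seed=3)


def dense_counts_map(counts: np.ndarray, track_id="t", **kw) -> ContactMap:
    """ContactMap from a symmetric dense count matrix (all loci available)."""
    n = counts.shape[0]
    entries = {
        (i, j): float(counts[i, j])
        for i in range(n) for j in range(i + 1, n)
        if counts[i, j] != 0
    }
    return ContactMap(track_id, n, entries, available=np.ones(n, dtype=bool), **kw)


def random_rotation(rng) -> np.ndarray:
    from scipy.stats import special_ortho_group

    return special_ortho_group.rvs(3, random_state=np.random.RandomState(rng.integers(2**31)))
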