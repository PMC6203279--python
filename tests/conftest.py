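import numpy as np
import pandas as pd
import pytest

from tf3dnet.core_io import ContactMap, GenomeStructure, GenomicSite, \
    GenomicSiteSet


def symmetric_map(rng, n_bins, bin_size=5000, raw_mean=30.0):
    """Random symmetric contact map with positive entries everywhere."""
    norm = rng.gamma(2.0, 2.0, (n_bins, n_bins))
    norm = np.triu(norm) + np.triu(norm, 1).T
    raw = rng.poisson(raw_mean, (n_bins, n_bins))
    raw = np.triu(raw) + np.triu(raw, 1).T
    return ContactMap("chr1", bin_size, norm, raw)


def sites_at_bins(bins, tf_id="TF", bin_size=5000, chrom="chr1", bound=True,
                  width=200):
    sites = []
    for b in bins:
        center = int(b) * bin_size + bin_size // 2
        sites.append(GenomicSite(chrom, center - width // 2,
                                 center + width // 2, ".", tf_id, 0.0, None,
                                 bound))
    return GenomicSiteSet(tf_id, sites)


def string_structure(n_particles=20, n_models=3, step=2.0, chrom="chr1",
                     particle_size=100_000, compartment=None):
    """Deterministic straight-line structure (adjacent distance = step)."""
    xyz = np.zeros((n_particles, 3))
    xyz[:, 0] = np.arange(n_particles) * step
    models = np.stack([xyz.copy() for _ in range(n_models)])
    particles = pd.DataFrame({"chrom": [chrom] * n_particles,
                              "start": np.arange(n_particles) * particle_size})
    return GenomeStructure(models, particles, particle_size=particle_size,
                           compartment=compartment)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
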