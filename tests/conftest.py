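import numpy as np
import pytest

from chimpcensus import genio, pipeline, popsim
from chimpcensus.popsim import SimConfig


@pytest.fixture(scope="session")
def small_panel():
    """Four-subspecies reference panel at published drift, 4,000 sites."""
    cfg = SimConfig(n_sites=4_000, seed=11)
    return popsim.draw_reference_freqs(cfg)


@pytest.fixture(scope="session")
def demo(tmp_path_factory):
    """The simulated demo cohort plus one full census run over it."""
    out = tmp_path_factory.mktemp("demo")
    cfg = SimConfig(n_sites=12_000, seed=42)
    sim = pipeline.simulate_cohort(cfg, out / "sim")
    rc = pipeline.RunConfig(
        unknown_vcf=str(sim.unknown_vcf), panel_vcf=str(sim.panel_vcf),
        panel_labels=str(sim.panel_labels), metadata=str(sim.metadata),
        out_dir=str(out / "census"),
        outlier_threshold=pipeline.DEMO_OUTLIER_THRESHOLD, seed=7)
    summary = pipeline.run_census(rc)
    return {"sim": sim, "config": rc, "summary": summary,
            "out": out / "census"}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_matrix(rng, n_samples=8, n_sites=50, missing=0.1):
    """Small random GenotypeMatrix with missing entries, for oracle tests."""
    d = rng.integers(0, 3, size=(n_samples, n_sites)).astype(np.int8)
    d[rng.random(d.shape) < missing] = popsim.MISSING
    return genio.matrix_from_arrays(
        {f"s{i:02d}": d[i] for i in range(n_samples)})
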