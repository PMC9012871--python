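import numpy as np
import pytest

from shallowcn.bins import BinScheme, annotate_bins, build_fixed_bins, mask_bins
from shallowcn.genome import GenomeLayout, Track
from shallowcn.normalize import build_panel
from shallowcn.simulate import (
    SimConfig,
    build_simulated_scheme,
    simulate_depth,
    simulate_reference,
)


@pytest.fixture(scope="session")
def small_sim():
    """Small but realistic simulated reference: 6 chromosomes x 20 Mb."""
    cfg = SimConfig(seed=42, n_chromosomes=6, chromosome_length=20_000_000)
    layout, gc_track, map_track = simulate_reference(cfg)
    scheme = build_simulated_scheme(cfg, layout, gc_track, map_track)
    return cfg, layout, gc_track, map_track, scheme


@pytest.fixture(scope="session")
def small_panel(small_sim):
    cfg, layout, _, _, scheme = small_sim
    rng = np.random.default_rng(7)
    controls = [
        simulate_depth(cfg, scheme, 0.0, None, rng, f"control_{i}") for i in range(9)
    ]
    pon = build_panel(controls, scheme)
    return controls, pon


@pytest.fixture()
def toy_layout():
    return GenomeLayout([("chr1", 1_000_000), ("chr2", 600_000)])


@pytest.fixture()
def uniform_track(toy_layout):
    t = Track()
    for name, length in toy_layout.chromosomes:
        t.add(name, [0], [length], [1.0])
    return t


def make_flat_scheme(n_bins_per_chrom=100, n_chrom=2, width=10_000, gc=0.45):
    """Fully annotated, unmasked fixed-width scheme for unit tests."""
    layout = GenomeLayout([(f"chr{i + 1}", n_bins_per_chrom * width) for i in range(n_chrom)])
    scheme = build_fixed_bins(layout, width)
    gc_track, map_track = Track(), Track()
    for name, length in layout.chromosomes:
        gc_track.add(name, [0], [length], [gc])
        map_track.add(name, [0], [length], [1.0])
    scheme = annotate_bins(scheme, gc_track, map_track)
    return mask_bins(scheme, 0.9)
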