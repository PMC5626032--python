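import pytest

from sinkassay import SyntheticSpec, WellGroup, simulate_plate


@pytest.fixture
def canonical_tsv(tmp_path):
    """Minimal canonical kinetic export: 3 reads, wells A1/A2."""
    p = tmp_path / "plate.tsv"
    p.write_text(
        "time_min\tA1\tA2\n"
        "0\t100\t80\n"
        "10\t50\t40\n"
        "20\t25\t20\n"
    )
    return p


@pytest.fixture
def catalog_csv(tmp_path):
    p = tmp_path / "catalog.csv"
    p.write_text(
        "well,species,growth_phase,replicate_group,plate_format\n"
        "A1,S. marinoi,exponential,rep1,96\n"
        "A2,S. marinoi,exponential,rep1,96\n"
        "A3,S. marinoi,exponential,rep1,96\n"
    )
    return p


@pytest.fixture
def two_pop_plate():
    """Simulated triplicate plate of two-subpopulation wells (defaults)."""
    groups = [
        WellGroup(
            name="mix",
            species="S. synthetica",
            growth_phase="exponential",
            wells=("A1", "A2", "A3"),
            spec=SyntheticSpec(seed=11),
        )
    ]
    return simulate_plate(groups, seed=11)


@pytest.fixture
def single_pop_plate():
    """Simulated plate of single-population (one-phase) wells.

    Uses the scattered-signal regime typical of low-density cultures
    (noise ~4% of the initial amplitude): with high signal-to-noise the
    residual curvature of the inverse-square decay is itself detectable
    and the breakpoint test correctly prefers two segments.
    """
    spec = SyntheticSpec(weights=(1.0,), s_values=(0.004,), noise_sd=40.0, seed=1)
    groups = [
        WellGroup(
            name="mono",
            species="T. synthetica",
            growth_phase="stationary",
            wells=("B1", "B2", "B3"),
            spec=spec,
        )
    ]
    return simulate_plate(groups, seed=1)
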