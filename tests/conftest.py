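import pytest

from resvar import Coupling, SyntheticMsaSpec, build_profile, simulate_msa


@pytest.fixture
def toy_rows():
    """Four aligned rows, reference first, with a gap and an ambiguity code."""
    return [
        ("ref", "MKT-AYIAK"),
        ("s1", "MKTPAYIAK"),
        ("s2", "MRT-AWIAK"),
        ("s3", "MKT-AXI-K"),
    ]


@pytest.fixture
def toy_profile(toy_rows):
    return build_profile(toy_rows, reference_id="ref", reference_offset=1)


@pytest.fixture
def planted_spec():
    """A family with two single-site supports, one coupling and one forbidden pair."""
    return SyntheticMsaSpec(
        reference="MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSR",
        n_sequences=400,
        seed=11,
        background_rate=0.02,
        supports={5: ("W", 0.25), 10: ("K", 0.40), 20: ("A", 0.30)},
        couplings=(
            Coupling(5, "W", 12, "P", 0.6),
            Coupling(10, "K", 20, "A", 0.0),  # jointly forbidden pair
        ),
    )


@pytest.fixture
def planted_family(planted_spec):
    rows, truth = simulate_msa(planted_spec)
    profile = build_profile(rows, reference_id="reference")
    return profile, truth
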