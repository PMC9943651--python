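import pytest

from psbind import binding, synthetic_data

DEFAULT_PATTERN = [
    "Rp", "Rp", "mixed", "Rp", "Sp", "Rp", "Rp",
    "Sp", "mixed", "Rp", "mixed", "Rp", "Rp", "Rp",
]


@pytest.fixture(scope="session")
def strand_spec():
    return synthetic_data.FixtureSpec(
        n_nucleotides=15, stereo_pattern=list(DEFAULT_PATTERN), seed=11
    )


@pytest.fixture(scope="session")
def strand_model(strand_spec):
    return synthetic_data.build_ps_strand(strand_spec)


@pytest.fixture(scope="session")
def strand_map(strand_model):
    return synthetic_data.render_anomalous_map(strand_model, noise=0.0, seed=0)


@pytest.fixture(scope="session")
def true_params():
    return binding.BindingParams(k_d=9.3, a0=0.10, da=0.15, ns=0.02)


@pytest.fixture(scope="session")
def clean_triplicate(true_params):
    return binding.simulate_titration(true_params, noise_sd=0.0, seed=0)


def bisection_bound_complex(prot_total, rna_total, k_d, ns=0.0, tol=1e-15):
    """Independent oracle: bisection on k_d*x - (P'-x)(R-x) = 0 over
    x in [0, min(P', R)]."""
    pp = prot_total * (1.0 - ns)
    r = rna_total
    if pp <= 0 or r <= 0:
        return 0.0
    f = lambda x: k_d * x - (pp - x) * (r - x)
    lo, hi = 0.0, min(pp, r)
    if f(hi) <= 0:
        return hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) <= 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(hi, 1e-30):
            break
    return 0.5 * (lo + hi)
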