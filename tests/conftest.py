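import numpy as np
import pytest

from coevodyn import (
    MsaGenSpec,
    RawAlignment,
    TrajGenSpec,
    ModeSpec,
    gen_msa,
    gen_trajectory,
    trivial_weighting,
)


@pytest.fixture
def toy_msa():
    """Four sequences with a perfectly covarying binary column pair (0, 1)."""
    return RawAlignment(
        ["s1", "s2", "s3", "s4"], ["ATG", "ATG", "LVG", "LVG"]
    )


@pytest.fixture
def toy_wa(toy_msa):
    return trivial_weighting(toy_msa)


@pytest.fixture
def planted_msa():
    spec = MsaGenSpec(
        n_seq=400, n_col=20, coupled_pairs=[(3, 11, 0.9)], seed=11
    )
    aln, truth = gen_msa(spec)
    return trivial_weighting(aln), truth


@pytest.fixture
def planted_traj():
    spec = TrajGenSpec(
        n_res=20,
        n_frames=2500,
        dt=0.01,
        modes=[
            ModeSpec(support=[2, 3], amplitude=0.3, kind="double_well", barrier=4.0),
            ModeSpec(support=[10, 11, 12], amplitude=0.5, kind="gaussian"),
            ModeSpec(support=[16, 17], amplitude=0.2, kind="harmonic",
                     wavenumber=100.0),
        ],
        noise_sd=0.02,
        seed=7,
    )
    return gen_trajectory(spec)


def gotoh_local(a, b, score, gap_open, gap_extend):
    """Independent affine-gap Smith–Waterman oracle (Gotoh recursion).

    A gap of length L costs gap_open + (L-1)*gap_extend. Returns the optimal
    local score only.
    """
    n, m = len(a), len(b)
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (moving along b)
    F = np.full((n + 1, m + 1), NEG)  # gap in b
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + score(a[i - 1], b[j - 1])
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best
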