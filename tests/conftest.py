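"""Shared fixtures and independent oracles for the test suite."""

import random

import pytest

from pcps import EnumerationParams, Substrate, get_substrate
from pcps.core import classify_order

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def kras_2_14() -> Substrate:
    return get_substrate("KRAS_G12V_2-14")


@pytest.fixture(scope="session")
def kras_1_21() -> Substrate:
    return get_substrate("KRAS_G12V_1-21")


@pytest.fixture(scope="session")
def rac2() -> Substrate:
    return get_substrate("RAC2_P29L_20-44")


def brute_force_psps(substrate: Substrate, params: EnumerationParams):
    """Independent oracle: naive double loop over all fragment pairs with
    post-hoc filtering.  Local coordinates; returns (i, j, k, l, order, seq)."""
    L = substrate.L
    frags = [(i, j) for i in range(1, L + 1) for j in range(i, L + 1)]
    gmax = params.max_gap if params.max_gap is not None else L
    out = []
    for (i, j) in frags:
        for (k, l) in frags:
            p1, p2 = j - i + 1, l - k + 1
            if not (params.min_part <= p1 <= params.max_part):
                continue
            if not (params.min_part <= p2 <= params.max_part):
                continue
            if not (params.min_len <= p1 + p2 <= params.max_len):
                continue
            order = classify_order(i, j, k, l)
            if order == "normal":
                gap = k - j - 1
                if gap < max(params.min_gap, 1) or gap > gmax:
                    continue
            elif order == "inverse":
                if params.order_mode == "normal":
                    continue
                gap = i - l - 1
                if gap < params.min_gap or gap > gmax:
                    continue
            else:  # overlapping
                if params.order_mode != "all":
                    continue
            seq = substrate.sequence[i - 1:j] + substrate.sequence[k - 1:l]
            if params.exclude_substrate_substrings and seq in substrate.sequence:
                continue
            out.append((i, j, k, l, order, seq))
    return out


def random_case(rng: random.Random):
    """One random (substrate, params) pair with L <= 12 and valid limits."""
    L = rng.randint(2, 12)
    alphabet = AA20[: rng.randint(2, 20)]
    seq = "".join(rng.choice(alphabet) for _ in range(L))
    min_part = rng.randint(1, 3)
    max_part = rng.randint(min_part, 6)
    min_len = rng.randint(2 * min_part, max(2 * min_part, 10))
    max_len = rng.randint(min_len, 14)
    min_gap = rng.randint(0, 2)
    max_gap = rng.choice([None, min_gap, min_gap + 2, 5])
    params = EnumerationParams(
        min_part=min_part, max_part=max_part, min_len=min_len, max_len=max_len,
        min_gap=min_gap, max_gap=max_gap,
        order_mode=rng.choice(["normal", "normal+inverse", "all"]),
        exclude_substrate_substrings=rng.choice([True, False]),
    )
    return Substrate("rnd", seq), params
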