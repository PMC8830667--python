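import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
import yaml

import vaxcov as vc


# ---------------------------------------------------------------------------
# independent oracles


def enumerate_coverage(p, v, D):
    """Exhaustive enumeration oracle for the coverage product.

    Enumerates every pass/fail combination of the n*D barrier-dose events
    under independence with exact rational arithmetic, checks the outcome
    probabilities sum to 1, and returns P(vaccinated) as 1 minus the
    enumerated failure mass — a computational path independent of the
    closed-form product.
    """
    fails = [Fraction(pi) * (1 - Fraction(vi)) for pi, vi in zip(p, v)] * D
    total = Fraction(0)
    not_vaccinated = Fraction(0)
    for combo in itertools.product((0, 1), repeat=len(fails)):
        prob = Fraction(1)
        for passed, f in zip(combo, fails):
            prob *= (1 - f) if passed else f
        total += prob
        if not all(combo):
            not_vaccinated += prob
    assert total == 1
    return float(1 - not_vaccinated)


def enumerate_coverage_grid(p_vectors, v_vectors, doses):
    """Vectorised enumeration oracle for large grids (float arithmetic).

    Same construction as :func:`enumerate_coverage` — sum the probability
    of every not-all-pass event combination — but chunked with numpy so
    full 5-point grids stay fast.
    """
    results = {}
    for D in doses:
        n = len(p_vectors[0])
        k = n * D
        bits = np.array(
            list(itertools.product((0.0, 1.0), repeat=k)), dtype=float
        )  # (2^k, k); 1 = pass
        cases = np.array(
            [np.tile(np.asarray(p) * (1 - np.asarray(v)), D)
             for p in p_vectors for v in v_vectors]
        )  # (C, k) failure probabilities
        vacc = np.all(bits == 1.0, axis=1)
        out = np.empty(len(cases))
        chunk = max(1, int(2e7 // bits.size))
        for start in range(0, len(cases), chunk):
            f = cases[start : start + chunk]  # (c, k)
            factors = bits[None] * (1 - f[:, None, :]) + (1 - bits[None]) * f[:, None, :]
            probs = factors.prod(axis=2)  # (c, 2^k)
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
            out[start : start + chunk] = 1.0 - probs[:, ~vacc].sum(axis=1)
        idx = 0
        for p in p_vectors:
            for v in v_vectors:
                results[(tuple(p), tuple(v), D)] = out[idx]
                idx += 1
    return results


# ---------------------------------------------------------------------------
# worked-example fixtures (three barriers, two barriers)


@pytest.fixture
def population_a3():
    """Three-barrier population: pass probabilities 80%, 50%, 50%."""
    return vc.PopulationProfile(("b1", "b2", "b3"), [0.20, 0.50, 0.50])


@pytest.fixture
def presentation_l3():
    """Least-desirable presentation on three barriers, single dose."""
    return vc.VaccinePresentation(("b1", "b2", "b3"), [0.0, 0.0, 0.0], 1)


@pytest.fixture
def presentation_t3():
    """Test presentation lifting pass probabilities to 100%, 80%, 50%."""
    return vc.VaccinePresentation(("b1", "b2", "b3"), [1.0, 0.6, 0.0], 1)


@pytest.fixture
def calibration_example():
    """Two-barrier worked example with every intermediate known exactly."""
    profile = vc.PopulationProfile(("b1", "b2"), [0.2, 0.5])
    calib = vc.VaccinePresentation(("b1", "b2"), [0.5, 0.5], 1)
    test = vc.VaccinePresentation(("b1", "b2"), [1.0, 0.8], 1)
    exact = {
        "U_c": Fraction(27, 40),
        "U_l": Fraction(16, 625),
        "S": Fraction(4, 13),
        "beta": Fraction(77, 130),
        "C_l": Fraction(9753, 16250),
        "k": Fraction(2436, 8125),
        "U_t": Fraction(9, 10),
        "x_t": Fraction(125, 1218),
        "C_t": Fraction(113, 130),
    }
    return dict(profile=profile, calib=calib, test=test, M=0.9, C_c=0.8, d_worst=4, exact=exact)


# ---------------------------------------------------------------------------
# synthetic scenario fixtures


def write_scenario(tmp_path, dataset, *, test_presentations, channels=None, sensitivity=None,
                   extra_presentations=None, d_worst=4):
    """Write a dataset plus config to disk; return the config path."""
    data_dir = tmp_path / "data"
    if extra_presentations is not None:
        pres, doses = extra_presentations
        dataset = vc.SyntheticDataset(
            regions=dataset.regions,
            indicators=dataset.indicators,
            presentations=pd.concat([dataset.presentations, pres], ignore_index=True),
            doses=pd.concat([dataset.doses, doses], ignore_index=True),
            truth=dataset.truth,
        )
    dataset.write(data_dir)
    cfg = dict(
        barriers=list(vc.BARRIERS),
        calibration_presentation="calibration_sc",
        test_presentations=list(test_presentations),
        regions_csv=str(data_dir / "regions.csv"),
        indicators_csv=str(data_dir / "indicators.csv"),
        presentations_csv=str(data_dir / "presentations.csv"),
        doses_csv=str(data_dir / "doses.csv"),
        d_worst=d_worst,
    )
    if channels is not None:
        cfg["channels"] = channels
    if sensitivity is not None:
        cfg["sensitivity"] = sensitivity
    path = tmp_path / "scenario.yaml"
    path.write_text(yaml.safe_dump(cfg))
    return path


def perfect_presentation_frames():
    """A presentation with every score at High and a single dose."""
    rows = [
        {
            "presentation_id": "perfect",
            "barrier_id": b,
            "variant": "pork_product" if b == "acceptability" else "",
            "level": "High",
        }
        for b in vc.BARRIERS
    ]
    doses = [{"presentation_id": "perfect", "doses_required": 1}]
    return pd.DataFrame(rows), pd.DataFrame(doses)


@pytest.fixture
def small_dataset():
    return vc.generate_dataset(vc.SyntheticSpec(n_countries=6, seed=11))
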