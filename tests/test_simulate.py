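"""Integration behaviour: nullity, conservation, convergence, monotonicity."""

import numpy as np
import pytest

from thrombosim import (
    DonorConcentrationProfile,
    SimulationConfig,
    conserved_totals,
    simulate,
    summarize,
)
from thrombosim.scheme import PROFILE_SPECIES, SchemeError


def test_no_tissue_factor_no_viia_means_no_cascade(model, reference_profile):
    """Without TF and trace FVIIa there is no initiation: every activated
    species stays identically zero."""
    prof = reference_profile.replace(TF=0.0, FVIIa=0.0)
    traj = simulate(prof, model.scheme, model.rates, model.sim)
    zymogens = set(PROFILE_SPECIES)
    for s in model.scheme.species:
        series = traj[s]
        if s in zymogens:
            assert np.all(series == series[0]), s
        else:
            assert np.all(series == 0.0), s


def test_free_viia_alone_cannot_initiate(model, reference_profile):
    """Free FVIIa has no catalytic role off the TF surface, so TF = 0 with
    the default trace FVIIa still yields zero thrombin."""
    traj = simulate(
        reference_profile.replace(TF=0.0), model.scheme, model.rates, model.sim
    )
    assert summarize(traj, theta=model.theta)["peak_FIIa"] == 0.0
    assert np.all(traj["FIIa"] == 0.0)


def test_lineage_conservation_on_reference(model, reference_profile):
    traj = simulate(reference_profile, model.scheme, model.rates, model.sim)
    totals = conserved_totals(traj)
    assert set(totals) == {"II", "V", "VII", "VIII", "IX", "X", "TF", "TFPI", "AT"}
    for lineage, series in totals.items():
        assert series[0] > 0, lineage
        drift = np.abs(series - series[0]).max() / series[0]
        assert drift < 1e-6, lineage


def test_unknown_lineage_rejected(model, reference_profile):
    traj = simulate(reference_profile, model.scheme, model.rates, model.sim)
    with pytest.raises(SchemeError, match="XII"):
        conserved_totals(traj, lineages=("XII",))


def test_nonnegativity_within_clip_tolerance(model, random_profiles):
    for prof in random_profiles[:5]:
        traj = simulate(prof, model.scheme, model.rates, model.sim)
        assert traj.concentrations.min() >= -model.sim.clip_tol


def test_peak_thrombin_monotone_in_prothrombin(model, reference_profile):
    peaks = []
    for s in (0.5, 1.0, 1.5, 2.0):
        prof = reference_profile.replace(FII=reference_profile["FII"] * s)
        traj = simulate(prof, model.scheme, model.rates, model.sim)
        peaks.append(summarize(traj, theta=model.theta)["peak_FIIa"])
    assert np.all(np.diff(peaks) >= 0)


def test_time_to_peak_monotone_in_tissue_factor(model, reference_profile):
    ttps = []
    for s in (0.5, 1.0, 1.5, 2.0):
        prof = reference_profile.replace(TF=reference_profile["TF"] * s)
        traj = simulate(prof, model.scheme, model.rates, model.sim)
        ttps.append(summarize(traj, theta=model.theta)["time_to_peak_FIIa"])
    assert np.all(np.diff(ttps) <= 0)


def test_removing_inhibitors_never_reduces_thrombin(model, random_profiles):
    for prof in random_profiles[:5]:
        with_inh = summarize(
            simulate(prof, model.scheme, model.rates, model.sim), theta=model.theta
        )
        without = summarize(
            simulate(
                prof.replace(TFPI=0.0, AT=0.0), model.scheme, model.rates, model.sim
            ),
            theta=model.theta,
        )
        assert without["peak_FIIa"] >= with_inh["peak_FIIa"]
        assert without["thrombin_AUC"] >= with_inh["thrombin_AUC"]


def test_tolerance_refinement_converged(model, reference_profile):
    base = summarize(
        simulate(reference_profile, model.scheme, model.rates, model.sim),
        theta=model.theta,
    )
    tight = summarize(
        simulate(
            reference_profile,
            model.scheme,
            model.rates,
            SimulationConfig(rtol=model.sim.rtol / 10, atol=model.sim.atol / 10),
        ),
        theta=model.theta,
    )
    assert base["peak_FIIa"] == pytest.approx(tight["peak_FIIa"], rel=1e-3)
    assert base["time_to_peak_FIIa"] == pytest.approx(
        tight["time_to_peak_FIIa"], rel=1e-3
    )


def test_invalid_profile_rejected():
    with pytest.raises(SchemeError):
        DonorConcentrationProfile({"TF": float("nan")})
    with pytest.raises(SchemeError):
        DonorConcentrationProfile({"FII": -1e-9})
    with pytest.raises(SchemeError):
        DonorConcentrationProfile({"FXa": 1e-9})  # not a donor input


def test_horizon_must_be_positive(model, reference_profile):
    with pytest.raises(ValueError):
        simulate(
            reference_profile,
            model.scheme,
            model.rates,
            SimulationConfig(horizon_s=0.0),
        )


def test_trajectory_frame_export(model, reference_profile):
    traj = simulate(reference_profile, model.scheme, model.rates, model.sim)
    wide = traj.to_frame()
    assert wide.shape == (len(traj.time), 35)  # time + 34 species
    long = traj.to_frame(long=True)
    assert set(long.columns) == {"time_s", "species", "concentration_M"}
    assert len(long) == len(traj.time) * 34
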