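"""Desk-scale study profiles: the fixed synthetic-study conditions.

The forecasting experiments are defined on four synthetic patients whose
configurations are frozen here, together with the desk-scale forecaster
settings used throughout the test suite and the results script.  The
profiles play the role of the study's subjects: every analysis refers to
the same generated recordings.

Scale choices (52-bin grids, 256-wide feed-forward blocks, hundreds to a
few thousand training epochs rather than the 20 000-epoch production
default) are the package's desk-scale operating point; the production
defaults remain in :class:`betadrift.forecaster.ForecasterConfig`.

* ``nonlinear_patient`` — 60 days, regime-switching location drift between
  two attracting levels smoothed over ~3 days, pink minute noise.  The
  drift is predictable from two days of history (transition direction is
  visible) but is poorly captured by per-bin linear maps: the regime the
  attention forecaster is built for.
* ``linear_patient`` — 90 days, linear distribution-width drift with one
  frozen intra-day noise pattern, so the histogram sequence is a smooth
  deterministic function of the drift: the control regime in which the
  per-bin linear baseline is near-optimal.
* ``constant_patient`` — no drift, white minute noise: nothing to alarm on.
* ``two_epoch_patient`` — the nonlinear patient split into two 30-day
  aDBS setting epochs, for the multi-setting training regime.
"""

from __future__ import annotations

from .forecaster import ForecasterConfig
from .synthetic import SyntheticPatientConfig

# desk-scale model settings
DESK_N_BINS = 52
DESK_FFW = 256
DESK_EPOCHS_ORDERING = 500     # nonlinear-fixture trainings
DESK_EPOCHS_LINEAR = 2000      # linear-fixture trainings
DESK_EPOCHS_MULTI = 400        # multi-setting phase 1 / fine-tune
DESK_EPOCHS_MEMORIZE = 2000    # capacity check

NONLINEAR_PATIENT = SyntheticPatientConfig(
    n_days=60, drift_kind="nonlinear_regime", drift_scale=0.6,
    baseline_sigma=0.04, regime_smooth_days=3, regime_switch_prob=0.12,
    noise_alpha=1.0, patient_id="SYN-NL", seed=7)

LINEAR_PATIENT = SyntheticPatientConfig(
    n_days=90, drift_kind="linear", drift_target="scale", drift_scale=0.32,
    baseline_sigma=0.2, noise_alpha=0.0, frozen_noise=True,
    patient_id="SYN-LIN", seed=11)

CONSTANT_PATIENT = SyntheticPatientConfig(
    n_days=60, drift_kind="none", baseline_sigma=0.04, noise_alpha=0.0,
    patient_id="SYN-CONST", seed=5)

TWO_EPOCH_PATIENT = SyntheticPatientConfig(
    n_days=60, drift_kind="nonlinear_regime", drift_scale=0.6,
    baseline_sigma=0.04, regime_smooth_days=3, regime_switch_prob=0.12,
    noise_alpha=1.0, epochs=(30, 30), patient_id="SYN-2SET", seed=7)


def desk_config(horizon: int = 1, n_history: int = 2,
                epochs: int = DESK_EPOCHS_ORDERING,
                n_bins: int = DESK_N_BINS) -> ForecasterConfig:
    """Desk-scale forecaster configuration (architecture as in production)."""
    return ForecasterConfig(
        n_bins=n_bins, n_history=n_history, horizon=horizon,
        feedforward_width=DESK_FFW, epochs=epochs,
        finetune_epochs=epochs, eval_every=max(1, epochs // 4))
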