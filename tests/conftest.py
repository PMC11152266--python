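"""Shared fixtures.

The heavyweight fixture is ``trained_models``: a complete small-scale
pipeline (multi-system autoencoder + diffusion model trained on a
two-state ensemble) shared by every test that needs trained networks.  It
is session-scoped and built lazily, so unit-test-only runs never pay for
it.
"""

import numpy as np
import pytest

from idpdiff.autoencoder import AEConfig, AETrainConfig, train_autoencoder
from idpdiff.diffusion import (
    DDPMTrainConfig, EncodedSystem, NoiseNetConfig, build_schedule,
    encode_dataset, train_ddpm,
)
from idpdiff.synthdata import ToyModelSpec, generate_toy_sequence, sample_toy_ensemble

# study conditions for the shared trained pipeline: a 10-residue two-state
# peptide (30% extended) plus five single-state companions for AE training
TWO_STATE_WEIGHT = 0.3
CHAIN_LENGTH = 10
AE_EPOCHS = 70
DDPM_EPOCHS = 150


@pytest.fixture(scope="session")
def two_state_spec():
    return ToyModelSpec(two_state_weight=TWO_STATE_WEIGHT)


@pytest.fixture(scope="session")
def toy_spec():
    return ToyModelSpec()


@pytest.fixture(scope="session")
def target_sequence():
    return generate_toy_sequence(CHAIN_LENGTH, 11)


@pytest.fixture(scope="session")
def reference_ensemble(target_sequence, two_state_spec):
    """Held-out reference draw from the two-state model."""
    return sample_toy_ensemble(target_sequence, 2000, two_state_spec, seed=23)


@pytest.fixture(scope="session")
def trained_models(target_sequence, two_state_spec, toy_spec):
    """Train the full small-scale pipeline once per session.

    Returns a dict with the autoencoder (params + scaler), the latent
    scaler, the diffusion network, the schedule, the training systems and
    the logs.
    """
    systems = [sample_toy_ensemble(target_sequence, 3000, two_state_spec, seed=21)]
    for i in range(5):
        s = generate_toy_sequence(CHAIN_LENGTH, 100 + i)
        systems.append(sample_toy_ensemble(s, 600, toy_spec, seed=200 + i))
    val = [
        sample_toy_ensemble(target_sequence, 300, two_state_spec, seed=22),
        sample_toy_ensemble(generate_toy_sequence(CHAIN_LENGTH, 150), 300,
                            toy_spec, seed=151),
    ]
    ae_cfg = AETrainConfig(epochs=AE_EPOCHS, batch_size=32, n_frames=1000,
                           seed=0, lr=2e-3)
    ae, scaler, ae_log = train_autoencoder(systems, val, ae_cfg,
                                           AEConfig(width=64))
    enc_train, lscaler = encode_dataset([systems[0]], ae)
    enc_val = [EncodedSystem(val[0].sequence,
                             lscaler.forward(ae.encode(val[0].coords)))]
    sched = build_schedule(1000)
    ddpm_cfg = DDPMTrainConfig(epochs=DDPM_EPOCHS, batch_size=64,
                               n_frames=1500, seed=0, lr=2e-3)
    # width-64 2-block noise network; smaller widths underfit the two-state
    # latent distribution at this training length
    net, ddpm_log = train_ddpm(enc_train, enc_val, ddpm_cfg, sched,
                               NoiseNetConfig(width=64, blocks=2))
    return {
        "ae": ae, "scaler": scaler, "latent_scaler": lscaler, "net": net,
        "sched": sched, "systems": systems, "val": val,
        "ae_log": ae_log, "ddpm_log": ddpm_log,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
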