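"""Shared fixtures: desk-scale operators, spectra, phantoms, and one trained
network reused by the training-dependent tests."""

import numpy as np
import pytest

from dectunroll import (
    BasisImage,
    DEAMConfig,
    EnergyGrid,
    PhantomSpec,
    build_material_basis,
    build_spectrum,
    build_system_operator,
    desk_fan_geometry,
    desk_helical_geometry,
    make_dataset,
    make_phantom,
    polychromatic_forward,
    step_normalizer,
)
from dectunroll.metrics import idd_initializer
from dectunroll.network import UnrolledNet, NetworkConfig, UpdateBlockConfig
from dectunroll.training import TrainConfig, bvm_loss, train


@pytest.fixture(scope="session")
def fan_geom():
    return desk_fan_geometry()


@pytest.fixture(scope="session")
def fan_op(fan_geom):
    return build_system_operator(fan_geom)


@pytest.fixture(scope="session")
def helical_geom():
    return desk_helical_geometry()


@pytest.fixture(scope="session")
def helical_op(helical_geom):
    return build_system_operator(helical_geom)


@pytest.fixture(scope="session")
def ectx():
    """Energy grid, material basis and 90/140 kVp spectra."""
    grid = EnergyGrid()
    basis = build_material_basis(grid)
    spec = build_spectrum(90.0, 140.0, grid)
    return grid, basis, spec


@pytest.fixture(scope="session")
def Z_fan(fan_op, ectx):
    _, basis, spec = ectx
    return step_normalizer(fan_op, basis, spec)


@pytest.fixture(scope="session")
def insert_phantom(fan_geom, ectx):
    grid, basis, _ = ectx
    return make_phantom(PhantomSpec(scale=0.25), fan_geom, basis, grid)


@pytest.fixture(scope="session")
def noiseless_sino(fan_op, ectx, insert_phantom):
    _, basis, spec = ectx
    ct, _, _ = insert_phantom
    return polychromatic_forward(fan_op, spec, basis, ct)


@pytest.fixture(scope="session")
def tiny_ctx():
    """9-voxel fan instance with a 4-bin spectrum for gradient oracles."""
    geom = desk_fan_geometry(n=3, n_channels=7, n_views=10)
    op = build_system_operator(geom)
    grid = EnergyGrid(np.array([40.0, 50.0, 60.0, 70.0]))
    basis = build_material_basis(grid)
    from dectunroll import SpectrumPair
    spec = SpectrumPair(grid=grid,
                        I0=np.array([[50.0, 80.0, 40.0, 10.0],
                                     [10.0, 40.0, 80.0, 50.0]]))
    Z = step_normalizer(op, basis, spec)
    return geom, op, grid, basis, spec, Z


@pytest.fixture(scope="session")
def trained_ctx(fan_geom, fan_op, ectx, Z_fan):
    """Dataset with IDD initializers plus a 1-block net pretrained 30 epochs.

    32 training and 8 held-out noisy insert-phantom samples; the network is
    the one the unrolling-sanity and initialization-study tests exercise.
    """
    grid, basis, spec = ectx
    data = make_dataset(
        40, PhantomSpec(scale=0.25), fan_geom, fan_op, spec, basis, grid,
        seed=7, noise="poisson",
        initializer=lambda d: idd_initializer(d, fan_op, spec, basis))
    train_set, val_set = data[:32], data[32:]
    net = UnrolledNet(NetworkConfig(n_blocks=1,
                                  block=UpdateBlockConfig(n_chl=8)),
                    (64, 64, 1), seed=3)
    result = train(train_set, net, TrainConfig(pretrain_epochs=30, seed=3),
                   "pretrain", fan_op, spec, basis, Z_fan,
                   val_dataset=val_set)
    idd_val_loss = float(np.mean(
        [bvm_loss(s.target.c, s.init.c, basis, spec.psi_L) for s in val_set]))
    return {
        "train_set": train_set,
        "val_set": val_set,
        "net": net,
        "result": result,
        "idd_val_loss": idd_val_loss,
    }
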