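import numpy as np
import pytest

from flow4d.flowsynth import FRAME_DT, FlowSolver, InflowProfile
from flow4d.geometry import make_idealized_geometry


def steady_profile(q: float = 3.0, period: float = 1.0) -> InflowProfile:
    times = np.arange(0.0, period - 1e-9, FRAME_DT)
    return InflowProfile(times=times, flow_rate=np.full_like(times, q),
                         period=period, label=f"steady{q}")


@pytest.fixture(scope="session")
def straight_solver():
    geom = make_idealized_geometry("straight", diameter=4.0, length=20.0, n_points=41)
    return FlowSolver(geom, 0.4, min_shape=32)


@pytest.fixture(scope="session")
def steady_tube_field(straight_solver):
    """Steady Poiseuille-like flow in a straight 4 mm tube, Q = 3 mL/s."""
    return straight_solver.solve(steady_profile(3.0), n_frames=1)


def toy_train(seed: int, epochs: int = 3, swa_epochs: int = 0):
    """Tiny but complete training run: 2 fields, small net, a few epochs."""
    from flow4d.enhancer import TrainSchedule, train
    from flow4d.flowsynth import make_inflow_profiles
    from flow4d.mriforward import AcquisitionConfig
    from flow4d.nn import NetworkConfig

    geoms = [make_idealized_geometry("straight", diameter=3.5, length=14.0,
                                     n_points=29),
             make_idealized_geometry("taper", diameter_in=3.5, diameter_out=2.5,
                                     length=14.0, n_points=29)]
    profiles = make_inflow_profiles(1, seed=5)
    fields = [FlowSolver(g, 0.5, min_shape=36).solve(profiles[0], n_frames=2,
                                                     label=g.label)
              for g in geoms]
    acq = AcquisitionConfig(venc_fraction_range=(0.9, 1.0),
                            snr_range=(30.0, 100.0), crop_factor=0.25,
                            background_ratio_range=(0.0, 1.0), rotate=False)
    cfg = NetworkConfig(n_residual_blocks=2, channels=8, dilations=(1, 2))
    return train(fields, acq_config=acq, net_config=cfg,
                 schedule=TrainSchedule(epochs=epochs, lr_max=4e-3,
                                        swa_epochs=swa_epochs), seed=seed)


@pytest.fixture(scope="session")
def toy_training_run():
    return toy_train(seed=123)
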