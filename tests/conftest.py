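import numpy as np
import pytest

import tastemg as tm


@pytest.fixture(scope="session")
def subject1() -> tm.SubjectProfile:
    return tm.SubjectProfile("S1")


@pytest.fixture(scope="session")
def config42() -> tm.GeneratorConfig:
    return tm.GeneratorConfig(seed=42)


@pytest.fixture(scope="session")
def salty_trials(subject1, config42):
    """Default synthetic Salty dataset: 1 subject, 2 sessions (12 trials)."""
    return tm.generate_dataset([subject1], 2, config42, tastes=["Salty"])


@pytest.fixture(scope="session")
def salty_table(salty_trials):
    """Feature table of the default Salty dataset (540 windows x 330 features)."""
    return tm.feature_table(salty_trials)


@pytest.fixture(scope="session")
def salty_windows(salty_trials):
    """Fully preprocessed kept windows of the default Salty dataset."""
    windows = []
    for trial in salty_trials:
        kept, _, _ = tm.preprocess_trial(trial)
        windows.extend(kept)
    return windows


@pytest.fixture(scope="session")
def all_taste_windows(subject1, config42):
    """Raw (augment-only) windows covering all 5 tastes x 6 intensities."""
    trials = tm.generate_dataset([subject1], 1, config42)
    windows = []
    for trial in trials:
        windows.extend(tm.augment_windows(trial))
    return windows


def make_window(signal_row: np.ndarray, n_channels: int = 6, fs: float = 1000.0,
                labels: dict | None = None) -> tm.WindowSample:
    """A window with the same 1-D signal on every channel."""
    sig = np.tile(np.asarray(signal_row, dtype=float), (n_channels, 1))
    return tm.WindowSample(sig, "fixture", 0, fs, labels or {})
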