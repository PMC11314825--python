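import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def write_wfdb_fixture(directory, name="synth01", n_sig=2, fs=128.0,
                       n_samples=7680, gain=200.0, baseline=0, fmt="16",
                       seed=0):
    """Write a tiny synthetic WFDB record (.hea + .dat) for reader tests.

    Returns (record path without extension, adc array (n_samples, n_sig)).
    """
    rng = np.random.default_rng(seed)
    adc = rng.integers(-2000, 2000, size=(n_samples, n_sig), dtype=np.int64)
    dat = directory / f"{name}.dat"
    if fmt == "16":
        dat.write_bytes(adc.astype("<i2").tobytes())
    elif fmt == "212":
        flat = adc.reshape(-1)
        if flat.size % 2:
            flat = np.concatenate([flat, [0]])
        first = np.where(flat[0::2] < 0, flat[0::2] + 4096, flat[0::2])
        second = np.where(flat[1::2] < 0, flat[1::2] + 4096, flat[1::2])
        packed = np.empty(3 * first.size, dtype=np.uint8)
        packed[0::3] = first & 0xFF
        packed[1::3] = ((first >> 8) & 0x0F) | (((second >> 8) & 0x0F) << 4)
        packed[2::3] = second & 0xFF
        dat.write_bytes(packed.tobytes())
    else:
        raise ValueError(fmt)
    lines = [f"{name} {n_sig} {fs:g} {n_samples}"]
    for ch in range(n_sig):
        lines.append(
            f"{name}.dat {fmt} {gain:g}({baseline})/mV 12 0 0 0 0 ECG{ch}"
        )
    (directory / f"{name}.hea").write_text("\n".join(lines) + "\n")
    return directory / name, adc
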