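"""Sensor scale-factor arithmetic for a 16-bit IMU front end.

The MPU-6050 class of parts digitizes each axis with a signed 16-bit ADC,
so a programmable full-scale range FS maps to 2**15 counts: the
sensitivity is 2**15 / FS least-significant bits per physical unit.
"""

STANDARD_GRAVITY = 9.8  # m/s², the benchmark value used throughout


def accel_lsb_per_g(full_scale_g: float = 4.0, adc_bits: int = 16) -> float:
    """Accelerometer sensitivity in LSB per g for a ±``full_scale_g`` range.

    With the default ±4 g range and 16-bit conversion this is
    32768 / 4 = 8192 LSB/g.
    """
    if full_scale_g <= 0:
        raise ValueError(f"full-scale range must be positive, got {full_scale_g}")
    return float(2 ** (adc_bits - 1)) / full_scale_g


def gyro_lsb_per_dps(full_scale_dps: float = 2000.0, adc_bits: int = 16) -> float:
    """Gyroscope sensitivity in LSB per °/s for a ±``full_scale_dps`` range.

    With the default ±2000 °/s range and 16-bit conversion this is
    32768 / 2000 = 16.384 LSB/(°/s).
    """
    if full_scale_dps <= 0:
        raise ValueError(f"full-scale range must be positive, got {full_scale_dps}")
    return float(2 ** (adc_bits - 1)) / full_scale_dps
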