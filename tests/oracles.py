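"""Independent brute-force oracles used only by the tests."""

import numpy as np


def sliding_window(imgs: np.ndarray, se: np.ndarray, op: str) -> np.ndarray:
    """Brute-force sliding-window min/max morphology with background borders.

    ``imgs`` may be a single (H, W) image or a batch (N, H, W); ``se`` must
    have odd dimensions (origin at the centre).  ``op='min'`` is erosion,
    ``op='max'`` is dilation; pixels outside the image count as background.
    """
    single = imgs.ndim == 2
    imgs = np.asarray(imgs, dtype=bool)
    if single:
        imgs = imgs[None]
    se = np.asarray(se, dtype=bool)
    h, w = se.shape
    assert h % 2 == 1 and w % 2 == 1, "oracle requires odd structuring elements"
    oh, ow = h // 2, w // 2
    n, rows, cols = imgs.shape
    padded = np.zeros((n, rows + h - 1, cols + w - 1), dtype=bool)
    padded[:, oh : oh + rows, ow : ow + cols] = imgs
    windows = np.stack(
        [
            padded[:, di : di + rows, dj : dj + cols]
            for di in range(h)
            for dj in range(w)
            if se[di, dj]
        ]
    )
    out = windows.all(axis=0) if op == "min" else windows.any(axis=0)
    return out[0] if single else out


def erosion_oracle(img, se):
    return sliding_window(img, se, "min")


def dilation_oracle(img, se):
    return sliding_window(img, se, "max")


def closing_oracle(img, se):
    return sliding_window(sliding_window(img, se, "max"), se, "min")


def mixture_phasor(fractions, taus, mod_freq_hz):
    """FD response of an intensity-weighted mixture of single-exponential decays.

    Returns (phi, M) from the summed phasor: G = sum a_i/(1+(w t_i)^2),
    S = sum a_i (w t_i)/(1+(w t_i)^2).
    """
    omega = 2 * np.pi * mod_freq_hz
    fractions = np.asarray(fractions, dtype=float)
    fractions = fractions / fractions.sum()
    wt = omega * np.asarray(taus, dtype=float) * 1e-9
    g = np.sum(fractions / (1 + wt**2))
    s = np.sum(fractions * wt / (1 + wt**2))
    return np.arctan2(s, g), float(np.hypot(g, s))
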