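"""Two-dimensional wavelet scattering transform.

Cascaded Morlet-wavelet convolutions with modulus nonlinearities and a
Gaussian low pass, computed in the Fourier domain. The transform yields
translation-invariant (to the subsampling scale ``2^J``) and
deformation-stable coefficients used as the handcrafted branch of the
hybrid cell-level model.

Numerical guarantees by construction:

* band-pass filters have their DC bin zeroed, so constant inputs produce
  exactly zero first- and second-order coefficients;
* convolutions are periodic FFT products, so a circular shift of the input
  by ``2^J`` pixels shifts the subsampled coefficients by one sample with
  unchanged values;
* the filter bank is normalised so its Littlewood-Paley sum is at most 1,
  which (with modulus preserving the L2 norm and subsampling only dropping
  samples) makes the whole transform non-expansive in energy.
"""

from __future__ import annotations

import numpy as np

_XI0 = 3.0 * np.pi / 4.0  # centre frequency of the mother wavelet
_SIGMA0 = 0.8             # spatial width of the mother wavelet


class Scattering2D:
    """Order-0..2 scattering coefficients on a fixed ``size x size`` grid.

    Parameters
    ----------
    size:
        Input side length; must be divisible by ``2**J``.
    J:
        Number of dyadic scales; output maps are ``size / 2**J`` on a side.
    L:
        Number of wavelet orientations over ``[0, pi)``.
    order:
        Maximum scattering order (0, 1 or 2). Second-order paths are
        restricted to ``j2 > j1`` (lower-frequency second wavelets), the
        paths that carry non-negligible energy.
    """

    def __init__(self, size: int, J: int = 2, L: int = 4, order: int = 2) -> None:
        if order not in (0, 1, 2):
            raise ValueError("order must be 0, 1 or 2")
        if size % (2 ** J) != 0:
            raise ValueError(f"size {size} not divisible by 2^J = {2 ** J}")
        self.size, self.J, self.L, self.order = size, J, L, order
        self._build_filters()

    def _build_filters(self) -> None:
        n = self.size
        wy = 2.0 * np.pi * np.fft.fftfreq(n)[:, None]
        wx = 2.0 * np.pi * np.fft.fftfreq(n)[None, :]
        psis = {}
        for j in range(self.J):
            s = _SIGMA0 * (2.0 ** j)
            for ell in range(self.L):
                theta = np.pi * ell / self.L
                xy = (_XI0 / 2.0 ** j) * np.cos(theta)
                yx = (_XI0 / 2.0 ** j) * np.sin(theta)
                psi = np.exp(-0.5 * s * s * ((wx - xy) ** 2 + (wy - yx) ** 2))
                psi[0, 0] = 0.0  # analytic zero response to constants
                psis[(j, ell)] = psi
        sJ = _SIGMA0 * (2.0 ** self.J)
        phi = np.exp(-0.5 * sJ * sJ * (wx ** 2 + wy ** 2))
        # Littlewood-Paley normalisation: kappa <= 1 everywhere
        kappa = phi ** 2 + sum(p ** 2 for p in psis.values())
        norm = np.sqrt(max(kappa.max(), 1.0))
        self.phi_hat = phi / norm
        self.psi_hat = {k: v / norm for k, v in psis.items()}

    # -- internals ----------------------------------------------------------

    def _lowpass_subsample(self, x: np.ndarray) -> np.ndarray:
        k = 2 ** self.J
        sm = np.fft.ifft2(np.fft.fft2(x) * self.phi_hat).real
        return sm[::k, ::k]

    def _modulus(self, x: np.ndarray, j: int, ell: int) -> np.ndarray:
        return np.abs(np.fft.ifft2(np.fft.fft2(x) * self.psi_hat[(j, ell)]))

    # -- public API ---------------------------------------------------------

    def path_names(self) -> list[str]:
        names = ["S0"]
        if self.order >= 1:
            names += [f"S1_j{j}t{l}" for j in range(self.J) for l in range(self.L)]
        if self.order >= 2:
            for j1 in range(self.J):
                for l1 in range(self.L):
                    for j2 in range(j1 + 1, self.J):
                        for l2 in range(self.L):
                            names.append(f"S2_j{j1}t{l1}_j{j2}t{l2}")
        return names

    @property
    def n_paths(self) -> int:
        return len(self.path_names())

    def transform(self, image: np.ndarray) -> np.ndarray:
        """Scattering coefficients of one ``size x size`` image.

        Returns an array of shape ``(n_paths, size / 2^J, size / 2^J)``.
        """
        image = np.asarray(image, dtype=float)
        if image.shape != (self.size, self.size):
            raise ValueError(f"expected {(self.size, self.size)} input, got {image.shape}")
        out = [self._lowpass_subsample(image)]
        if self.order >= 1:
            u1 = {}
            for j1 in range(self.J):
                for l1 in range(self.L):
                    u = self._modulus(image, j1, l1)
                    u1[(j1, l1)] = u
                    out.append(self._lowpass_subsample(u))
            if self.order >= 2:
                for (j1, l1), u in u1.items():
                    for j2 in range(j1 + 1, self.J):
                        for l2 in range(self.L):
                            out.append(self._lowpass_subsample(self._modulus(u, j2, l2)))
        return np.stack(out)

    def transform_batch(self, crops: np.ndarray) -> np.ndarray:
        """Scattering of a ``(B, C, size, size)`` stack, channels flattened
        into paths: output ``(B, C * n_paths, size/2^J, size/2^J)``."""
        b, c = crops.shape[:2]
        k = self.size // 2 ** self.J
        out = np.empty((b, c * self.n_paths, k, k))
        for i in range(b):
            for ch in range(c):
                out[i, ch * self.n_paths:(ch + 1) * self.n_paths] = \
                    self.transform(crops[i, ch])
        return out
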