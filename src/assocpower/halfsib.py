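"""Closed-form matrix algebra for balanced half-sib designs.

With f equal families of d half-sibs every matrix appearing in the analytic
moments (A, D, H = I - J/n, the MME block Cuu, and their products and
inverses) lies in the commutative algebra spanned by {I, B, J}, where B is
the block-diagonal all-ones matrix over families and J the all-ones matrix.
Its elements are diagonalised by the same three invariant subspaces:

* within-family contrasts  (multiplicity n - f),
* between-family contrasts (multiplicity f - 1),
* the all-ones vector      (multiplicity 1).

Representing a matrix by its three eigenvalues makes every trace and
quadratic form O(1), so designs with thousands of animals cost nothing;
correctness against the dense path is covered by tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ExchangeableMatrix"]


@dataclass(frozen=True)
class ExchangeableMatrix:
    f: int  # number of families
    d: int  # family size
    e_w: float  # eigenvalue on within-family contrasts
    e_b: float  # eigenvalue on between-family contrasts
    e_g: float  # eigenvalue on the all-ones vector

    # --- constructors -------------------------------------------------
    @classmethod
    def from_abc(cls, f: int, d: int, a: float, b: float, c: float) -> "ExchangeableMatrix":
        """Matrix a*I + b*B + c*J."""
        n = f * d
        return cls(f, d, a, a + b * d, a + b * d + c * n)

    @classmethod
    def identity(cls, f: int, d: int) -> "ExchangeableMatrix":
        return cls(f, d, 1.0, 1.0, 1.0)

    @classmethod
    def relationship(cls, f: int, d: int) -> "ExchangeableMatrix":
        """Half-sib A: 1 on the diagonal, 1/4 within family, 0 across."""
        return cls.from_abc(f, d, 0.75, 0.25, 0.0)

    @classmethod
    def mendelian(cls, f: int, d: int) -> "ExchangeableMatrix":
        """Half-sib D = I/2."""
        return cls.from_abc(f, d, 0.5, 0.0, 0.0)

    @classmethod
    def centering(cls, f: int, d: int) -> "ExchangeableMatrix":
        """H = I - J/n."""
        return cls(f, d, 1.0, 1.0, 0.0)

    # --- algebra ------------------------------------------------------
    @property
    def n(self) -> int:
        return self.f * self.d

    def _like(self, e_w, e_b, e_g) -> "ExchangeableMatrix":
        return ExchangeableMatrix(self.f, self.d, e_w, e_b, e_g)

    def _check(self, other) -> None:
        if (self.f, self.d) != (other.f, other.d):
            raise ValueError("mismatched design dimensions")

    def __add__(self, other):
        if np.isscalar(other):  # scalar means other * I... disallow ambiguity
            raise TypeError("add ExchangeableMatrix, not scalar")
        self._check(other)
        return self._like(self.e_w + other.e_w, self.e_b + other.e_b, self.e_g + other.e_g)

    def __sub__(self, other):
        self._check(other)
        return self._like(self.e_w - other.e_w, self.e_b - other.e_b, self.e_g - other.e_g)

    def __matmul__(self, other):
        self._check(other)
        return self._like(self.e_w * other.e_w, self.e_b * other.e_b, self.e_g * other.e_g)

    def __mul__(self, scalar):
        return self._like(scalar * self.e_w, scalar * self.e_b, scalar * self.e_g)

    __rmul__ = __mul__

    def inv(self) -> "ExchangeableMatrix":
        if min(abs(self.e_w), abs(self.e_b), abs(self.e_g)) < 1e-300:
            raise np.linalg.LinAlgError("singular exchangeable matrix")
        return self._like(1.0 / self.e_w, 1.0 / self.e_b, 1.0 / self.e_g)

    # --- scalar functionals -------------------------------------------
    def trace(self) -> float:
        return (self.n - self.f) * self.e_w + (self.f - 1) * self.e_b + self.e_g

    def quad_ones(self) -> float:
        """1' M 1."""
        return self.n * self.e_g

    # --- conversion ----------------------------------------------------
    def dense(self) -> np.ndarray:
        d, f, n = self.d, self.f, self.n
        a = self.e_w
        b = (self.e_b - self.e_w) / d
        c = (self.e_g - self.e_b) / n
        B = np.kron(np.eye(f), np.ones((d, d)))
        return a * np.eye(n) + b * B + c * np.ones((n, n))
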