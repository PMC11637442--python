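"""Independent reference implementations used as oracles by the tests.

Deliberately coded differently from the package (per-angle lookup tables
instead of basis vectors) so that agreement is informative.
"""

from __future__ import annotations

import math


class TabularKalman:
    """Per-position tabular Kalman-filter learner for one-hot encodings.

    Keeps one value and one variance entry per distinct angle and feature
    dimension.  Matches the function-approximation learner when the basis is
    (numerically) one-hot, i.e. very large concentration with stimuli on the
    node grid.
    """

    def __init__(self, alpha_s, alpha_f, m_s, m_f, mean_update, c, sigma):
        self.alpha = [alpha_s, alpha_f]
        self.m = [m_s, m_f]
        self.mean_update = mean_update
        self.c = c
        self.sigma = sigma
        self.values = [{}, {}]  # angle -> value, per dimension
        self.variances = [{}, {}]

    def _v(self, dim, angle):
        return self.values[dim].get(angle, 25.0)

    def _var(self, dim, angle):
        return self.variances[dim].get(angle, 5.0)

    def value(self, s, f):
        return self._v(0, s) + self._v(1, f)

    def uncertainty(self, s, f):
        return self._var(0, s), self._var(1, f)

    def accept_prob(self, s, f):
        u_s, u_f = self.uncertainty(s, f)
        va = self.value(s, f) + self.c * (u_s + u_f)
        return 0.5 * (1.0 + math.erf((va - 50.0) / (self.sigma * math.sqrt(2.0))))

    @staticmethod
    def _rate(u, m):
        if math.isinf(m):
            return 0.0
        return u / (u + m) if u + m > 0 else 0.0

    def learn(self, s, f, reward):
        delta = reward - self.value(s, f)
        u_pre = self.uncertainty(s, f)
        for dim, angle in ((0, s), (1, f)):
            self.values[dim][angle] = self._v(dim, angle) + self.alpha[dim] * delta
            self.variances[dim][angle] = self._var(dim, angle) * (1.0 - self.alpha[dim])
        if self.mean_update:
            a = self._rate(0.5 * (u_pre[0] + u_pre[1]), self.m[0])
            self.alpha = [a, a]
        else:
            self.alpha = [self._rate(u_pre[0], self.m[0]), self._rate(u_pre[1], self.m[1])]
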