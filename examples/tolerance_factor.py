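"""How the tolerance-interval factor rewards additional runs.

The factor sqrt(nu (1 + 1/N) / chi2_{alpha,nu}) multiplies a model's
residual standard deviation wherever the integrated process model draws
noise, so it quantifies how much a unit operation's uncertainty shrinks as
training runs accumulate.
"""

from hdoe import ToleranceSettings, tolerance_factor, tolerance_interval

settings = ToleranceSettings(coverage=0.99, confidence=0.05)

print("N    nu   factor")
for n in (6, 8, 12, 23, 50, 200):
    p = 5  # a five-term model
    print(f"{n:<5d}{n - p:<5d}{tolerance_factor(n, n - p, settings):.3f}")

lo, hi = tolerance_interval(y_hat=3.8, sigma=0.1, n=12, nu=7,
                            settings=settings)
print(f"\n99%-coverage tolerance interval at N=12: [{lo:.3f}, {hi:.3f}]")
print("The factor drops steeply over the first runs and flattens toward 1:")
print("beyond ~20 runs per unit operation, extra DoE runs buy little.")
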