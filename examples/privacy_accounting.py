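"""Track the privacy cost of DP training with the Rényi accountant.

Four collaborating institutions train for 30 epochs at batch size 32 with
noise multiplier sigma = 1.4.  Each client's epsilon at delta = 1e-5 depends
only on its training-set size: more data means a smaller sampling rate and a
tighter guarantee, which is why pooled training is the most private row.
"""

from proxyfl import epsilon_for_training

sizes = {"C1": 2338, "C2": 2726, "C3": 2937, "C4": 2841}
sizes["pooled"] = sum(sizes.values())

print(f"{'client':>8}  {'N':>6}  epsilon (sigma=1.4, delta=1e-5, 30 epochs, B=32)")
for name, n in sizes.items():
    eps = epsilon_for_training(N=n, B=32, epochs=30, sigma=1.4, delta=1e-5)
    print(f"{name:>8}  {n:>6}  {eps:.3f}")

print("\nSmaller epsilon = stronger privacy; epsilon grows with the sampling "
      "rate B/N and the number of composed steps.")
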