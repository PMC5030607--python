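"""From scan and event logs to dyadic networks and proximity-bond classes.

Builds the directed proximity duration matrix (minutes within 10 m per
co-party hour), modality-specific gesture rate matrices, classifies bonds
by the mean +/- half-SD rule, and reports normalised degree centrality.
"""
import gestnet as g

ds = g.simulate_dataset(n=12, seed=1)
prox = g.proximity_duration_matrix(ds.scans, ds.labels)

off = prox.offdiag_values()
print(f"proximity matrix: {prox.n}x{prox.n}, {off.size} directed dyads")
print(f"  mean {off.mean():.1f} min/hr, SD {off.std():.1f} (values bounded by [0, 60])")

bonds = g.classify_bonds(prox, "preferred_reciprocated")
print(f"bond thresholds: upper {bonds.upper_threshold:.2f}, "
      f"lower {bonds.lower_threshold:.2f} min/hr")
frac = bonds.base.offdiag_values().mean()
print(f"preferred, reciprocated bonds: {100 * frac:.1f}% of directed dyads")

vis = g.gesture_rate_matrix(ds.events, ds.scans, modality="visual", labels=ds.labels)
print(f"visual gesture rates: mean {vis.offdiag_values().mean():.2f} events/hr "
      "(per hour the recipient was within 10 m)")

# degree centrality of the strong-bond network: each individual's share of
# possible strong ties
strong = g.classify_bonds(prox, "strong").base
deg = g.normalized_degree(strong, "out")
print("strong-bond out-degree (% of possible ties):")
print((100 * deg).round(1).to_string())
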