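"""Generate a seeded release pair and check the engine against ground truth.

The fixture generator builds a schema-valid miniature database, samples a
conflict-free edit script (citations, typos, merges, GO annotations, new
objects), and derives the exact set of subscriptions that must fire via an
independent brute-force oracle.  The notification engine is then run on the
same pair and compared.
"""

from pgdbnotify import apply_script, generate_base, random_script, run_notifications, sample_registry

SEED = 22


def main() -> None:
    old = generate_base(seed=SEED)
    registry = sample_registry(old, SEED)
    script = random_script(old, SEED, n_edits=8)
    new, truth = apply_script(old, script, registry)

    print(f"base snapshot: {len(old.objects)} objects; registry: {len(registry.entries)} subscriptions")
    print("edit script:", ", ".join(e.kind for e in script.edits))

    fired = {item.subscription for item in run_notifications(registry, old, new)}
    print(f"engine fired {len(fired)} subscriptions; oracle expected {len(truth.fired)}")
    print("exact agreement:", fired == truth.fired)
    for sub in sorted(fired):
        print(f"  {sub.user}  {sub.kind}  {sub.target_id}  {sub.mode}")


if __name__ == "__main__":
    main()
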