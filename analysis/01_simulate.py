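"""Generate the synthetic study dataset: four tissue groups along the
adenoma-carcinoma sequence with planted trajectory classes, purity-confounded
mixtures and beta-distributed noise.  Writes results/data/."""

from _common import DATA_DIR, load_or_simulate


def main() -> None:
    bm, ann, sheet, truth = load_or_simulate()
    counts = truth.probes["class"].value_counts()
    print(f"dataset: {bm.shape[0]} probes x {bm.shape[1]} samples -> {DATA_DIR}")
    print("samples per group:", sheet.frame["group"].value_counts().to_dict())
    print("planted classes:")
    for cls, n in counts.items():
        print(f"  {cls:>20}: {n}")
    changed = counts.drop(["stable_unmeth", "stable_meth"]).sum()
    print(f"planted modified fraction: {changed / len(truth.probes):.3f}")


if __name__ == "__main__":
    main()
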