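#!/usr/bin/env python
"""miRNA target filtering (score > 150 & energy < -15; energy < -15 &
p < 0.05; intersection of both predictors) and per-gene dominance calls
between promoter accessibility and miRNA repression."""

from triomics import run_stages

from common import OUT_DIR, load_inputs


def main() -> None:
    inputs = load_inputs()
    result = run_stages(**inputs)

    result.target_map.to_csv(OUT_DIR / "filtered_targets.tsv", sep="\t", index=False)
    print(f"target map: {len(result.target_map)} miRNA-gene pairs survive the "
          f"two-predictor intersection (from {len(inputs['target_records'])} raw records)")

    result.tension_calls.to_csv(OUT_DIR / "tension_calls.tsv", sep="\t", index=False)
    calls = result.tension_calls["call"].value_counts()
    print("regulatory dominance calls over promoter-peak genes:")
    print(calls.to_string())
    md = result.tension_calls.query("call == 'mirna_dominant'")
    if len(md):
        print(f"-> {len(md)} downregulated genes with opened promoters are "
              f"explained by upregulated miRNAs (repression beat accessibility)")


if __name__ == "__main__":
    main()
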