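#!/usr/bin/env python
"""Extended segregation and control screening of the transcribed candidates.

Loads the 22 validated candidate variants, applies the published extended
co-segregation calls, screens the three perfectly segregating candidates with
the published control-cohort carrier counts (16 and 8 heterozygous carriers
among 1,600 controls for the PDCD6IP and LIPJ variants; none for DNAJC5), and
ranks the shortlist.

Writes results/shortlist.tsv.
"""

import argparse
from pathlib import Path

from ancl_exome.segregation import ControlScreenResult, shortlist
from ancl_exome.variant_io import load_candidate_table

PUBLISHED_CARRIERS = {"PDCD6IP": 16, "LIPJ": 8, "DNAJC5": 0}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cands = load_candidate_table()
    print(f"{len(cands)} validated candidates "
          f"({sum(c.call.is_indel for c in cands)} indels); "
          f"{sum(bool(c.segregation_flag) for c in cands)} segregate perfectly")

    screens = {
        c.key: ControlScreenResult(
            c.key, 1600, PUBLISHED_CARRIERS.get(c.call.gene, 0), 0
        )
        for c in cands
    }
    ranked = shortlist(cands, screens)
    lines = ["rank\tgene\taa_subst\tcarriers_of_1600\tcarrier_freq\tallele_freq"]
    print("\nshortlist after the 1,600-control screen:")
    for i, c in enumerate(ranked, start=1):
        scr = screens[c.key]
        print(f"  {i}. {c.call.gene:<8s} {c.aa_subst or c.call.alt:<8s} "
              f"carriers={scr.carrier_count:<3d} carrier_freq={scr.carrier_frequency:.4f} "
              f"allele_freq={scr.allele_frequency:.4f}")
        lines.append(
            f"{i}\t{c.call.gene}\t{c.aa_subst or c.call.alt}\t{scr.carrier_count}"
            f"\t{scr.carrier_frequency:.4f}\t{scr.allele_frequency:.4f}"
        )
    zero = [c for c in ranked if screens[c.key].carrier_count == 0]
    print(f"\ncandidates absent from all controls: "
          f"{', '.join(c.call.gene for c in zero)} "
          f"({'unique causative candidate' if len(zero) == 1 else 'not unique'})")
    (args.out / "shortlist.tsv").write_text("\n".join(lines) + "\n")


if __name__ == "__main__":
    main()
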