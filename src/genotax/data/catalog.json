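{
  "version": 1,
  "description": "Chemotype pathway catalog: gene symbols per pathway family, with the groupings the prediction rules reference. Symbols are unique to one family; rules in genotax.chemotax reference them symbolically.",
  "families": {
    "fatty_acid_synthesis": {
      "symbols": ["accA", "accB", "accC", "accD", "fabD", "fabH", "fabY", "fabB", "fabF", "fabG", "fabA", "fabZ", "fabI", "fabV"],
      "required_groups": [
        ["accA"], ["accB"], ["accC"], ["accD"],
        ["fabD"], ["fabH", "fabY"], ["fabB"], ["fabF"],
        ["fabG"], ["fabA"], ["fabZ"], ["fabI", "fabV"]
      ],
      "note": "Type II fatty acid synthesis (FASII). fabH/fabY are alternative 3-ketoacyl-ACP synthase III; fabI/fabV alternative enoyl-ACP reductases. fabA+fabB drive the anaerobic omega-7 mono-unsaturation branch."
    },
    "desaturase": {
      "symbols": ["Des1", "Des2", "Des3", "Des4"],
      "alternative_group": true,
      "note": "SCD-like delta-9 acyl desaturase homologs, one functional role; activity requires the HXXXH and HXXHH histidine clusters."
    },
    "lipid_a": {
      "symbols": ["lpxA"],
      "note": "LpxA incorporates 3-hydroxyacyl chains into lipid A (C10:0 3-OH)."
    },
    "pufa": {
      "symbols": ["pfaA", "pfaB", "pfaC", "pfaD", "oleA", "oleB", "oleC", "oleD"],
      "note": "Polyunsaturated fatty acid synthase complexes; absence implies no PUFA."
    },
    "polar_lipid": {
      "symbols": ["plsX", "plsY", "plsC", "cdsA", "pssA", "psd", "pgsA", "pgpA", "cls"],
      "backbone": ["plsX", "plsY", "plsC", "cdsA"],
      "pe_branch": ["pssA", "psd"],
      "pg_branch": ["pgsA", "pgpA"],
      "dpg": ["cls"]
    },
    "quinone": {
      "symbols": ["ubiC", "ubiA", "ubiD", "ubiX", "ubiI", "ubiG", "ubiH", "ubiE", "ispA", "ispB", "ubiB", "ubiJ", "ubiK", "ubiF"],
      "pathway": ["ubiC", "ubiA", "ubiD", "ubiX", "ubiI", "ubiG", "ubiH", "ubiE", "ispA", "ispB"],
      "accessory": ["ubiB", "ubiJ", "ubiK", "ubiF"],
      "note": "Q-8 biosynthesis; ispB (octaprenyl-diphosphate synthase) fixes the side-chain length at 8 isoprene units. Accessory factors are required in vivo but mechanistically uncertain; ubiF is kept accessory pending user review."
    },
    "polyamine": {
      "symbols": ["speA", "speB", "speC", "speD", "speE", "spuC", "kauB"],
      "agmatine_route": ["speA", "speB"],
      "ornithine_route": ["speC"],
      "spermidine": ["speD", "speE"],
      "gaba_route": ["spuC", "kauB"]
    },
    "phb": {
      "symbols": ["phaA", "phaB", "phaC", "phaE"],
      "note": "Acetyl-CoA to poly-beta-hydroxybutyrate."
    },
    "transport": {
      "symbols": ["dctM", "dctP", "dctQ", "tctA", "tctB", "tctC", "yejA", "yejB", "yejE", "yejF"],
      "report_only": true,
      "note": "C4-dicarboxylate TRAP (dctMPQ), tricarboxylate (tctABC) and AMP-resistance ABC (yejABEF) transporters; reported as presence only, no chemotype rule."
    }
  }
}
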