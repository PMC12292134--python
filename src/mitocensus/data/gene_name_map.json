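{
  "_comment": "Normalization table from common mitochondrial gene aliases to the canonical symbols used throughout this package. Keys are matched case-insensitively after stripping anticodon parentheses. Editable: pass a custom mapping to normalize_gene_name / the parsers.",
  "cob": "cytb", "cytb": "cytb", "cyb": "cytb", "mt-cyb": "cytb",
  "nd1": "nad1", "nad1": "nad1", "mt-nd1": "nad1",
  "nd2": "nad2", "nad2": "nad2", "mt-nd2": "nad2",
  "nd3": "nad3", "nad3": "nad3", "mt-nd3": "nad3",
  "nd4": "nad4", "nad4": "nad4", "mt-nd4": "nad4",
  "nd4l": "nad4L", "nad4l": "nad4L", "mt-nd4l": "nad4L",
  "nd5": "nad5", "nad5": "nad5", "mt-nd5": "nad5",
  "nd6": "nad6", "nad6": "nad6", "mt-nd6": "nad6",
  "cox1": "cox1", "co1": "cox1", "coi": "cox1", "cox-1": "cox1", "mt-co1": "cox1",
  "cox2": "cox2", "co2": "cox2", "coii": "cox2", "cox-2": "cox2", "mt-co2": "cox2",
  "cox3": "cox3", "co3": "cox3", "coiii": "cox3", "cox-3": "cox3", "mt-co3": "cox3",
  "atp6": "atp6", "atpase6": "atp6", "mt-atp6": "atp6",
  "atp8": "atp8", "atpase8": "atp8", "mt-atp8": "atp8",
  "rrns": "rrnS", "12s": "rrnS", "12s rrna": "rrnS", "s-rrna": "rrnS", "12s ribosomal rna": "rrnS",
  "rrnl": "rrnL", "16s": "rrnL", "16s rrna": "rrnL", "l-rrna": "rrnL", "16s ribosomal rna": "rrnL",
  "d-loop": "D-loop", "dloop": "D-loop", "control region": "D-loop", "cr": "D-loop",
  "trna-phe": "trnF", "trnf": "trnF",
  "trna-val": "trnV", "trnv": "trnV",
  "trna-leu": "trnL2", "trnl": "trnL2", "trnl1": "trnL1", "trnl2": "trnL2",
  "trna-ile": "trnI", "trni": "trnI",
  "trna-gln": "trnQ", "trnq": "trnQ",
  "trna-met": "trnM", "trnm": "trnM",
  "trna-trp": "trnW", "trnw": "trnW",
  "trna-ala": "trnA", "trna": "trnA",
  "trna-asn": "trnN", "trnn": "trnN",
  "trna-cys": "trnC", "trnc": "trnC",
  "trna-tyr": "trnY", "trny": "trnY",
  "trna-ser": "trnS1", "trns": "trnS1", "trns1": "trnS1", "trns2": "trnS2",
  "trna-asp": "trnD", "trnd": "trnD",
  "trna-lys": "trnK", "trnk": "trnK",
  "trna-gly": "trnG", "trng": "trnG",
  "trna-arg": "trnR", "trnr": "trnR",
  "trna-his": "trnH", "trnh": "trnH",
  "trna-glu": "trnE", "trne": "trnE",
  "trna-thr": "trnT", "trnt": "trnT",
  "trna-pro": "trnP", "trnp": "trnP"
}
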