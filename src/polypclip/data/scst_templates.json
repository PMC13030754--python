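{
  "adenoma": {
    "entity": "A photo of an adenoma.",
    "quantification": "Exhibiting tubular or villous architecture with low-grade intraepithelial neoplasia.",
    "context": "Representing a common precancerous intestinal lesion.",
    "generic": "A photo of an adenoma."
  },
  "hyperplasia": {
    "entity": "A photo of a hyperplastic polyp.",
    "quantification": "Showing elongated crypts with a characteristic serrated or ’saw-tooth’ appearance.",
    "context": "Identified as a generally benign mucosal proliferation.",
    "generic": "A photo of hyperplasia."
  },
  "normal": {
    "entity": "A photo of normal intestinal mucosal tissue.",
    "quantification": "Characterized by regular crypt structures and smooth surface with no dysplasia.",
    "context": "Indicating healthy intestinal mucosa without abnormalities.",
    "generic": "A photo of normal mucosa."
  }
}
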