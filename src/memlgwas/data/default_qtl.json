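{
 "comment": "Default 43-QTL panel (15 major, 28 minor) for the gene-dropping simulation study; synthetic stand-in effects drawn once (fixed seed 987654321) so that at allele frequency 0.5 the major QTL jointly explain ~30% and the minor ~5% of phenotypic variance with residual variance 1. pos_frac is the relative position on the chromosome and is resolved to a SNP index for any grid size.",
 "residual_variance": 1.0,
 "population_mean": 1.0,
 "qtl": [
  {
   "chrom": 1,
   "pos_frac": 0.141878,
   "effect": 0.295897,
   "class": "major"
  },
  {
   "chrom": 1,
   "pos_frac": 0.432884,
   "effect": -0.124162,
   "class": "minor"
  },
  {
   "chrom": 1,
   "pos_frac": 0.533373,
   "effect": 0.014213,
   "class": "minor"
  },
  {
   "chrom": 1,
   "pos_frac": 0.655697,
   "effect": 0.03076,
   "class": "minor"
  },
  {
   "chrom": 1,
   "pos_frac": 0.7712,
   "effect": -0.046991,
   "class": "minor"
  },
  {
   "chrom": 1,
   "pos_frac": 0.879964,
   "effect": 0.187395,
   "class": "minor"
  },
  {
   "chrom": 1,
   "pos_frac": 0.956412,
   "effect": 0.038624,
   "class": "minor"
  },
  {
   "chrom": 2,
   "pos_frac": 0.050204,
   "effect": -0.190936,
   "class": "minor"
  },
  {
   "chrom": 2,
   "pos_frac": 0.15587,
   "effect": 0.075899,
   "class": "minor"
  },
  {
   "chrom": 2,
   "pos_frac": 0.277176,
   "effect": -0.056888,
   "class": "major"
  },
  {
   "chrom": 2,
   "pos_frac": 0.348603,
   "effect": 0.086231,
   "class": "major"
  },
  {
   "chrom": 2,
   "pos_frac": 0.361433,
   "effect": -0.094997,
   "class": "minor"
  },
  {
   "chrom": 2,
   "pos_frac": 0.433921,
   "effect": -0.053433,
   "class": "minor"
  },
  {
   "chrom": 2,
   "pos_frac": 0.455621,
   "effect": -0.073996,
   "class": "minor"
  },
  {
   "chrom": 2,
   "pos_frac": 0.52669,
   "effect": -0.059579,
   "class": "minor"
  },
  {
   "chrom": 2,
   "pos_frac": 0.534265,
   "effect": 0.416281,
   "class": "major"
  },
  {
   "chrom": 2,
   "pos_frac": 0.572096,
   "effect": -0.191621,
   "class": "major"
  },
  {
   "chrom": 2,
   "pos_frac": 0.749757,
   "effect": -0.299423,
   "class": "major"
  },
  {
   "chrom": 2,
   "pos_frac": 0.754317,
   "effect": -0.224601,
   "class": "major"
  },
  {
   "chrom": 3,
   "pos_frac": 0.08013,
   "effect": -0.11996,
   "class": "major"
  },
  {
   "chrom": 3,
   "pos_frac": 0.117458,
   "effect": -0.099573,
   "class": "major"
  },
  {
   "chrom": 3,
   "pos_frac": 0.378974,
   "effect": -0.032537,
   "class": "minor"
  },
  {
   "chrom": 3,
   "pos_frac": 0.412286,
   "effect": -0.037901,
   "class": "minor"
  },
  {
   "chrom": 3,
   "pos_frac": 0.827313,
   "effect": -0.037613,
   "class": "minor"
  },
  {
   "chrom": 3,
   "pos_frac": 0.909939,
   "effect": 0.019017,
   "class": "minor"
  },
  {
   "chrom": 4,
   "pos_frac": 0.296231,
   "effect": -0.019596,
   "class": "minor"
  },
  {
   "chrom": 4,
   "pos_frac": 0.494824,
   "effect": 0.067598,
   "class": "minor"
  },
  {
   "chrom": 4,
   "pos_frac": 0.564256,
   "effect": 0.032793,
   "class": "minor"
  },
  {
   "chrom": 4,
   "pos_frac": 0.855211,
   "effect": 0.058495,
   "class": "minor"
  },
  {
   "chrom": 5,
   "pos_frac": 0.06772,
   "effect": 0.507131,
   "class": "major"
  },
  {
   "chrom": 5,
   "pos_frac": 0.188357,
   "effect": -0.086943,
   "class": "major"
  },
  {
   "chrom": 5,
   "pos_frac": 0.196153,
   "effect": 0.135755,
   "class": "major"
  },
  {
   "chrom": 5,
   "pos_frac": 0.504859,
   "effect": 0.05997,
   "class": "minor"
  },
  {
   "chrom": 6,
   "pos_frac": 0.093383,
   "effect": -0.258844,
   "class": "major"
  },
  {
   "chrom": 6,
   "pos_frac": 0.261757,
   "effect": -0.278336,
   "class": "major"
  },
  {
   "chrom": 6,
   "pos_frac": 0.309517,
   "effect": -0.015391,
   "class": "minor"
  },
  {
   "chrom": 6,
   "pos_frac": 0.317231,
   "effect": -0.02696,
   "class": "minor"
  },
  {
   "chrom": 6,
   "pos_frac": 0.360622,
   "effect": 0.047444,
   "class": "minor"
  },
  {
   "chrom": 6,
   "pos_frac": 0.629357,
   "effect": -0.140421,
   "class": "major"
  },
  {
   "chrom": 6,
   "pos_frac": 0.666677,
   "effect": -0.088946,
   "class": "minor"
  },
  {
   "chrom": 6,
   "pos_frac": 0.691011,
   "effect": 0.044302,
   "class": "minor"
  },
  {
   "chrom": 6,
   "pos_frac": 0.852323,
   "effect": -0.015736,
   "class": "minor"
  },
  {
   "chrom": 6,
   "pos_frac": 0.878681,
   "effect": 0.069587,
   "class": "minor"
  }
 ]
}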