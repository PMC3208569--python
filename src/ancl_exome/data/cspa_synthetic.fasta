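>CSPA_SYNTHETIC synthetic CSP-alpha-like reference (198 aa); constructed stand-in, not the natural sequence; see docs/methods.md
MADQRQRSLSTSGESLYHVLGLDKNATSDDIKKSYRKLALKYHPDKNPDNPEAAEKFKEI
NNAHAILTDATKRNIYDKYGSLGLYVAEELSEDVVNSFKNFDILGNTAIFHACALLTCCA
CCCCNCCAWNWWWNKQKPKETDEEHARGAPEGSQEREVQDPNASAGGAQPGSAGGSRAGS
TQPSAGNGFHDDDDSDEE
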