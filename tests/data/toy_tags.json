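{"description": "full tag array of the toy graph, computed by the naive permute-by-suffix-array oracle; one (v,o,b) triple per BWT row", "tags": [[0, 1, 0], [0, 1, 0], [0, 1, 0], [0, 1, 0], [0, 1, 0], [0, 1, 0], [1, 0, 1], [1, 0, 1], [1, 0, 1], [4, 2, 1], [4, 2, 1], [4, 2, 1], [7, 4, 0], [7, 4, 0], [7, 4, 0], [2, 0, 0], [2, 0, 0], [7, 4, 1], [7, 4, 1], [3, 0, 0], [7, 1, 0], [7, 1, 0], [7, 1, 0], [7, 4, 1], [8, 1, 0], [8, 1, 0], [8, 1, 0], [1, 1, 1], [1, 1, 1], [1, 1, 1], [4, 3, 1], [4, 3, 1], [4, 3, 1], [8, 0, 1], [8, 0, 1], [8, 0, 1], [1, 1, 0], [1, 1, 0], [1, 1, 0], [2, 2, 0], [3, 2, 0], [2, 2, 0], [1, 3, 1], [1, 3, 1], [1, 3, 1], [4, 1, 1], [4, 1, 1], [4, 1, 1], [8, 0, 0], [8, 0, 0], [8, 0, 0], [2, 1, 0], [2, 1, 0], [7, 1, 1], [7, 1, 1], [4, 3, 0], [7, 1, 1], [6, 0, 1], [6, 0, 1], [4, 3, 0], [4, 3, 0], [3, 1, 1], [7, 2, 1], [7, 2, 1], [5, 0, 0], [7, 2, 1], [7, 3, 0], [7, 3, 0], [7, 3, 0], [1, 0, 0], [1, 0, 0], [1, 0, 0], [3, 1, 0], [4, 0, 1], [4, 0, 1], [4, 0, 1], [4, 2, 0], [4, 2, 0], [4, 2, 0], [7, 2, 0], [7, 2, 0], [7, 2, 0], [5, 0, 1], [2, 1, 1], [2, 1, 1], [6, 0, 0], [6, 0, 0], [8, 2, 1], [8, 2, 1], [8, 2, 1], [8, 2, 0], [8, 2, 0], [8, 2, 0], [2, 2, 1], [3, 2, 1], [2, 2, 1], [1, 3, 0], [1, 3, 0], [7, 3, 1], [7, 3, 1], [1, 3, 0], [7, 0, 0], [7, 0, 0], [7, 0, 0], [7, 3, 1], [1, 2, 1], [1, 2, 1], [1, 2, 1], [7, 0, 1], [7, 0, 1], [7, 0, 1], [3, 0, 1], [4, 1, 0], [4, 1, 0], [4, 1, 0], [2, 0, 1], [2, 0, 1], [8, 1, 1], [8, 1, 1], [8, 1, 1], [1, 2, 0], [1, 2, 0], [1, 2, 0], [4, 0, 0], [4, 0, 0], [4, 0, 0]]}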