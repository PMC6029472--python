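patient_id,diagnosis_detail,diagnosis_class,ratio,suv_max,pattern,diameter_cm,mitotic_count
1,High-grade LMS,malignant,4.388,11.1,hollow_ball,11.9,23
2,High-grade LMS,malignant,2.703,11.4,hollow_ball,5.5,25
3,High-grade LMS,malignant,1.707,11.4,hollow_ball,17.4,30
4,High-grade LMS,malignant,,11.4,hollow_ball,11.4,20
5,High-grade LMS,malignant,,11.8,hollow_ball,5.8,15
6,Low-grade LMS,malignant,5.533,4.3,hollow_ball,8.8,5
7,Low-grade LMS,malignant,1.421,3.7,hollow_ball,8.6,10
8,STUMP,malignant,2.036,5.4,hollow_ball,13.7,5
9,Ordinary leiomyoma,benign,1.063,2.2,diffuse_low,14.0,
10,Ordinary leiomyoma,benign,1.013,4.2,focal,6.5,
11,Ordinary leiomyoma,benign,0.964,4.0,heterogeneous,8.8,
12,Ordinary leiomyoma,benign,0.955,2.0,diffuse_low,16.0,
13,Ordinary leiomyoma,benign,0.896,3.1,heterogeneous,5.7,
14,Ordinary leiomyoma,benign,,6.0,focal,10.2,
15,Ordinary leiomyoma,benign,,5.8,heterogeneous,5.4,
16,Ordinary leiomyoma,benign,,3.9,focal,5.0,
17,Ordinary leiomyoma,benign,,3.5,focal,16.7,
18,Degenerated leiomyoma,benign,1.038,2.5,diffuse_low,10.2,
19,Degenerated leiomyoma,benign,,3.5,heterogeneous,11.6,
20,Cellular leiomyoma,benign,1.069,2.5,diffuse_low,7.9,
21,Infarcted leiomyoma,benign,1.034,9.4,diffuse_high,11.1,
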