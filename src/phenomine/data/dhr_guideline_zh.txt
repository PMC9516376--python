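Stevens-Johnson综合征
过敏性休克
药物超敏反应综合征
大疱表皮松解症
AS
EB
TEN
SJS
DIHS
过敏
超敏
黏膜
红斑
松解
喘鸣
支气管痉挛
发绀
呼气流量峰值下降
肌张力减退
荨麻疹
血管性水肿
紫绀
低血容量性低血压
斑疹
斑丘疹
无菌性脓疱
紫癜
剥脱性皮炎
融合成片
松弛性水疱
表皮松解
大疱
表皮剥脱
叶状鳞屑
表皮剥离
猩红热样
麻疹样
弥漫性
黏膜侵蚀
糖皮质激素
肾上腺素
甲基泼尼松龙
泼尼松
地塞米松
IVIG
甲泼尼龙
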